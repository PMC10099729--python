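"""Developmental splicing dynamics: posterior ΔΨ calls and entropy drift.

Each stage of a developmental series is compared against the earliest
(reference) stage. Per condition, Ψ gets a Beta posterior with a Jeffreys
prior on the event's inclusion/exclusion read counts; the posterior
probability that |ΔΨ| >= 0.1 is estimated by paired Monte-Carlo draws. An
event is a *Dev-event* when it is differentially spliced (|ΔΨ| >= 0.1 and
posterior >= 0.85) in at least five stages versus the reference. Separately,
events whose splicing entropy ranges over >= 0.5 bits across well-supported
stages (> 20 reads, host gene > 10 TPM, in >= 5 stages) are flagged
entropy-dynamic; the Dev x dynamic cross-tabulation quantifies how much
complexity change happens without inclusion-level change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "StageQuant",
    "StageSeries",
    "DeltaPsiCall",
    "delta_psi_posterior",
    "call_dev_events",
    "entropy_dynamic_flag",
    "dev_entropy_crosstab",
]


@dataclass
class StageQuant:
    """One developmental stage of one event."""

    stage: str
    ordinal: int
    incl: int
    excl: int
    entropy: float = math.nan
    psi: float = math.nan
    reads: int = 0
    tpm: float = math.nan


@dataclass
class StageSeries:
    event_id: str
    stages: list[StageQuant]
    reference_index: int = 0

    def __post_init__(self) -> None:
        ords = [s.ordinal for s in self.stages]
        if sorted(ords) != ords or len(set(ords)) != len(ords):
            raise ValueError(f"{self.event_id}: stages must be strictly ordered")
        if not 0 <= self.reference_index < len(self.stages):
            raise ValueError(f"{self.event_id}: reference stage missing")

    @property
    def reference(self) -> StageQuant:
        return self.stages[self.reference_index]


@dataclass
class DeltaPsiCall:
    stage: str
    delta_psi: float
    posterior: float
    significant: bool
    defined: bool = True


def delta_psi_posterior(
    ref_counts: tuple[int, int],
    stage_counts: tuple[int, int],
    delta: float = 0.1,
    posterior_min: float = 0.85,
    n_draws: int = 2000,
    seed: int | np.random.Generator = 0,
    prior: float = 0.5,
    stage: str = "",
) -> DeltaPsiCall:
    """Posterior differential-splicing call for one stage vs the reference.

    Ψ | counts ~ Beta(incl + prior, excl + prior) independently per
    condition; the posterior is the fraction of paired draws with
    |Ψ_stage − Ψ_ref| >= delta. The point estimate ΔΨ uses the posterior
    means. A condition with zero total reads yields an undefined call.
    """
    (ri, re), (si, se) = ref_counts, stage_counts
    if min(ri, re, si, se) < 0:
        raise ValueError("negative read counts")
    if ri + re == 0 or si + se == 0:
        return DeltaPsiCall(stage, math.nan, math.nan, False, defined=False)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    psi_ref = (ri + prior) / (ri + re + 2 * prior)
    psi_stage = (si + prior) / (si + se + 2 * prior)
    dpsi = psi_stage - psi_ref
    draws_ref = rng.beta(ri + prior, re + prior, size=n_draws)
    draws_stage = rng.beta(si + prior, se + prior, size=n_draws)
    posterior = float(np.mean(np.abs(draws_stage - draws_ref) >= delta))
    significant = abs(dpsi) >= delta and posterior >= posterior_min
    return DeltaPsiCall(stage, dpsi, posterior, significant)


def call_dev_events(
    series: StageSeries,
    min_significant_stages: int = 5,
    delta: float = 0.1,
    posterior_min: float = 0.85,
    n_draws: int = 2000,
    seed: int = 0,
) -> tuple[str | None, list[DeltaPsiCall]]:
    """Classify a series as 'Dev' / 'non-Dev' from per-stage ΔΨ calls.

    Dev requires a significant call in at least ``min_significant_stages``
    non-reference stages; a series with fewer quantifiable non-reference
    stages than that is unclassifiable (None).
    """
    rng = np.random.default_rng(seed)
    ref = series.reference
    calls = []
    for i, st in enumerate(series.stages):
        if i == series.reference_index:
            continue
        calls.append(
            delta_psi_posterior(
                (ref.incl, ref.excl),
                (st.incl, st.excl),
                delta=delta,
                posterior_min=posterior_min,
                n_draws=n_draws,
                seed=rng,
                stage=st.stage,
            )
        )
    defined = [c for c in calls if c.defined]
    if len(defined) < min_significant_stages:
        return None, calls
    n_sig = sum(c.significant for c in defined)
    return ("Dev" if n_sig >= min_significant_stages else "non-Dev"), calls


def entropy_dynamic_flag(
    series: StageSeries,
    min_change: float = 0.5,
    min_reads: int = 20,
    min_tpm: float = 10.0,
    min_stages: int = 5,
) -> bool:
    """True when entropy ranges >= ``min_change`` bits across eligible stages.

    Eligible stages have more than ``min_reads`` supporting reads and host
    gene expression above ``min_tpm``; at least ``min_stages`` stages must
    be eligible.
    """
    ents = [
        s.entropy
        for s in series.stages
        if s.reads > min_reads and s.tpm > min_tpm and not math.isnan(s.entropy)
    ]
    if len(ents) < min_stages:
        return False
    return (max(ents) - min(ents)) >= min_change


def dev_entropy_crosstab(
    events: Iterable[tuple[str | None, bool]],
) -> tuple[pd.DataFrame, float]:
    """2x2 counts of {Dev, non-Dev} x {dynamic, static} and the fraction of
    entropy-dynamic events among non-Dev events (nan when no non-Dev)."""
    table = pd.DataFrame(
        0, index=["Dev", "non-Dev"], columns=["dynamic", "static"], dtype=int
    )
    for status, dynamic in events:
        if status not in ("Dev", "non-Dev"):
            continue
        table.loc[status, "dynamic" if dynamic else "static"] += 1
    n_nondev = int(table.loc["non-Dev"].sum())
    ratio = (
        float(table.loc["non-Dev", "dynamic"] / n_nondev)
        if n_nondev
        else math.nan
    )
    return table, ratio
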