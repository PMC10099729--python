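"""Event classification and between-tissue class comparison.

An event in a sample is *alternative* when 0 < Ψ < 0.97 and *constitutive*
when Ψ >= 0.97 (given it passes the expression filters); events with
entropy >= 1.0 bits are flagged high-complexity (two or more effective
splicing outcomes; 1.5 is the stricter sensitivity cutoff). For pairwise
tissue comparison, events are placed in ten K{n}_{m} classes crossing
complexity (K1/K2/K3, with K>=3 folded into K3) with the Ψ level
(Low (0,0.2], Middle (0.2,0.8), High [0.8,0.97)); events quantifiable in
only one tissue of the pair fall into "Others", and events unquantifiable
in both are dropped from the comparison.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

__all__ = [
    "KNM_CLASSES",
    "splicing_status",
    "high_complexity_flag",
    "knm_class",
    "tissue_transition_table",
]

KNM_CLASSES = (
    "K1_Low", "K1_Middle", "K1_High",
    "K2_Low", "K2_Middle", "K2_High",
    "K3_Low", "K3_Middle", "K3_High",
    "Others",
)

PSI_CONSTITUTIVE = 0.97


def splicing_status(psi: float | None, passes_filter: bool) -> str:
    """'alternative' (0 < Ψ < 0.97), 'constitutive' (Ψ >= 0.97) or 'excluded'."""
    if psi is None or not passes_filter:
        return "excluded"
    if psi >= PSI_CONSTITUTIVE:
        return "constitutive"
    if 0.0 < psi < PSI_CONSTITUTIVE:
        return "alternative"
    return "excluded"  # psi == 0: never included here


def high_complexity_flag(entropy: float, threshold: float = 1.0) -> bool:
    """True when splicing entropy reaches the high-complexity threshold."""
    if entropy < 0:
        raise ValueError("entropy must be non-negative")
    return entropy >= threshold


def _in_category(psi: float | None, k_bin: int | None, quantifiable: bool) -> bool:
    return (
        quantifiable
        and psi is not None
        and k_bin is not None
        and k_bin >= 1
        and 0.0 < psi < PSI_CONSTITUTIVE
    )


def _psi_level(psi: float) -> str:
    if 0.0 < psi <= 0.2:
        return "Low"
    if 0.2 < psi < 0.8:
        return "Middle"
    return "High"  # 0.8 <= psi < 0.97


def knm_class(
    k_bin: int | None,
    psi: float | None,
    quantifiable_here: bool,
    quantifiable_other: bool,
    psi_other: float | None = None,
    k_bin_other: int | None = None,
) -> str | None:
    """Ten-class K{n}_{m} label for one tissue of a compared pair.

    Returns None when the event is dropped from the pair (unquantifiable or
    Ψ = 0 on both sides); "Others" when only the other tissue carries a
    classifiable observation.
    """
    if _in_category(psi, k_bin, quantifiable_here):
        k = min(k_bin, 3)  # type: ignore[arg-type]
        return f"K{k}_{_psi_level(psi)}"  # type: ignore[arg-type]
    if psi_other is None and k_bin_other is None:
        other_ok = quantifiable_other
    else:
        other_ok = _in_category(psi_other, k_bin_other, quantifiable_other)
    return "Others" if other_ok else None


def tissue_transition_table(
    events_a: Mapping[str, str | None], events_b: Mapping[str, str | None]
) -> pd.DataFrame:
    """10x10 contingency table of K{n}_{m} classes between two tissues.

    ``events_a``/``events_b`` map event ids to class labels (None = dropped);
    rows are tissue A classes, columns tissue B. Marginals equal the
    per-tissue class histograms of the retained pairs.
    """
    table = pd.DataFrame(
        0, index=list(KNM_CLASSES), columns=list(KNM_CLASSES), dtype=int
    )
    for ev, ca in events_a.items():
        cb = events_b.get(ev)
        if ca is None or cb is None:
            continue
        table.loc[ca, cb] += 1
    return table
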