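"""Independent brute-force oracles shared by tests."""


def single_change_explanations(states, tree):
    """Every (branch clade name, direction) whose implied leaf pattern equals
    the observed states; independent of the package's parsimony code."""
    out = []
    for clade in tree.clades:
        for direction, changed, base in (("gain", "A", "C"), ("loss", "C", "A")):
            implied = {
                sp: changed if sp in clade else base for sp in tree.leaves
            }
            if implied == states:
                out.append((tree.clade_name(clade), direction))
    return out
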