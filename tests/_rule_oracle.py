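"""Independent brute-force evaluation of the evidence-combination rule table.

This is a literal transcription of the published combining rules, kept
deliberately separate from the package implementation: every rule is one
explicit predicate over strength counts, and conflict resolution is applied
as a final step.  Used to cross-check the engine by exhaustive enumeration.
"""

PATH_STRENGTH = {
    "PVS1": "pvs",
    **{f"PS{i}": "ps" for i in range(1, 5)},
    **{f"PM{i}": "pm" for i in range(1, 7)},
    **{f"PP{i}": "pp" for i in range(1, 6)},
}
BENIGN_STRENGTH = {
    "BA1": "ba",
    **{f"BS{i}": "bs" for i in range(1, 5)},
    **{f"BP{i}": "bp" for i in range(1, 8)},
}


def combine_oracle(code_ids):
    """Classify a set of code identifiers: returns one of 'P','LP','VUS','LB','B'."""
    ids = set(code_ids)
    pvs = "PVS1" in ids
    ps = sum(1 for c in ids if PATH_STRENGTH.get(c) == "ps")
    pm = sum(1 for c in ids if PATH_STRENGTH.get(c) == "pm")
    pp = sum(1 for c in ids if PATH_STRENGTH.get(c) == "pp")
    ba = "BA1" in ids
    bs = sum(1 for c in ids if BENIGN_STRENGTH.get(c) == "bs")
    bp = sum(1 for c in ids if BENIGN_STRENGTH.get(c) == "bp")

    pathogenic_rules = [
        pvs and ps >= 1,
        pvs and pm >= 2,
        pvs and pm == 1 and pp == 1,
        pvs and pp >= 2,
        ps >= 2,
        ps == 1 and pm >= 3,
        ps == 1 and pm == 2 and pp >= 2,
        ps == 1 and pm == 1 and pp >= 4,
    ]
    likely_pathogenic_rules = [
        pvs and pm == 1,
        ps == 1 and pm in (1, 2),
        ps == 1 and pp >= 2,
        pm >= 3,
        pm == 2 and pp >= 2,
        pm == 1 and pp >= 4,
    ]
    benign_rules = [ba, bs >= 2]
    likely_benign_rules = [bs >= 1 and bp >= 1, bp >= 2]

    path_fired = any(pathogenic_rules) or any(likely_pathogenic_rules)
    benign_fired = any(benign_rules) or any(likely_benign_rules)
    any_path_code = pvs or ps or pm or pp
    any_benign_code = ba or bs or bp

    if path_fired and any_benign_code:
        return "VUS"
    if benign_fired and any_path_code:
        return "VUS"
    if any(pathogenic_rules):
        return "P"
    if any(likely_pathogenic_rules):
        return "LP"
    if any(benign_rules):
        return "B"
    if any(likely_benign_rules):
        return "LB"
    return "VUS"


#: The representative code panel enumerated exhaustively (2^11 subsets).
ENUMERATION_PANEL = (
    "PVS1", "PS1", "PM1", "PM3", "PP1", "PP3",
    "BA1", "BS1", "BS2", "BP2", "BP4",
)


def all_panel_subsets():
    n = len(ENUMERATION_PANEL)
    for bits in range(1 << n):
        yield tuple(
            ENUMERATION_PANEL[i] for i in range(n) if bits >> i & 1
        )
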