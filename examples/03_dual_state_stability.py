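"""Dual-state stability profiles: predictor ingestion, classes, consensus.

Builds per-variant open/closed ddG profiles from five predictors (written
here as toy tables), classifies each pattern at a 1 kcal/mol-style
threshold, and votes a consensus.  Negative ddG means destabilizing; a
positive open-state value reads as a shift toward the active conformation.
"""
from pathlib import Path
from tempfile import TemporaryDirectory

import varstate as vs

# three illustrative dual-state patterns
PATTERNS = {
    "p.A634D": (-3.0, -6.4),   # destabilizes both states (activating-like)
    "p.R879G": (+2.5, -1.2),   # open-state shift with closed destabilization
    "p.L100V": (-0.2, +0.1),   # neutral
}

with TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    records = []
    for i, predictor in enumerate(("SDM", "mCSM", "DUET", "DDMut", "Dynamut2")):
        for state, col in (("open", 0), ("closed", 1)):
            path = tmp / f"{predictor}_{state}.tsv"
            lines = ["variant\tddG"] + [
                # predictors disagree a little around the shared pattern
                f"{v}\t{vals[col] + 0.1 * (i - 2):.2f}"
                for v, vals in PATTERNS.items()
            ]
            path.write_text("\n".join(lines) + "\n")
            records.extend(vs.read_ddg_table(path, predictor, state))

    profiles = vs.build_profiles(records, tau=1.0)
    for label, (o, c) in PATTERNS.items():
        key = vs.parse_variant_label(label).key
        prof = profiles[key]
        print(f"{label}: open {o:+.1f}, closed {c:+.1f}")
        print(f"  per-predictor classes: "
              f"{sorted({cl.value for cl in prof.per_predictor_classes().values()})}")
        print(f"  consensus: {prof.consensus().value}, "
              f"detailed pattern: {vs.stability_pattern(o, c)}")

# The first pattern destabilizes both conformations — the signature of the
# known activating variants.  The second combines closed-state
# destabilization with a stabilizing open shift: both effects favor the
# catalytically active state, reported as the compound pattern.
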