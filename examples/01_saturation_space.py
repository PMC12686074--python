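"""Enumerate the complete single-residue substitution space of a protein.

Every residue of a 1154-residue kinase-sized protein is replaced with each
of the 19 alternative amino acids, giving the 19*L variant universe that
downstream scoring and clustering operate on.
"""
import numpy as np

import varstate as vs
from varstate.variants import AMINO_ACIDS

rng = np.random.default_rng(0)
residues = "".join(np.array(list(AMINO_ACIDS))[rng.integers(0, 20, 1154)])
protein = vs.ProteinSequence("demo_kinase", residues)

variant_space = vs.enumerate_saturation(protein)
print(f"protein length:       {protein.length} residues")
print(f"saturation variants:  {len(variant_space)}  (= 19 x {protein.length})")

# a single clinical-style label round-trips through the parser
v = vs.parse_variant_label("p.V464M")
print(f"parsed {v.label}: position {v.position}, {v.ref_aa} -> {v.alt_aa}")

# domain annotation against a user-supplied domain map
domains = vs.DomainMap(
    intervals=((34, 420, "FERM"), (439, 544, "SH2"), (583, 855, "PK"), (875, 1153, "TK"))
)
print(f"domain of position {v.position}: {vs.annotate_domain(v, domains)}")
# The counts above are the size of the search space a structure-informed
# screen must rank; the domain label localizes a variant within the protein.
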