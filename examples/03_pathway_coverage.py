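"""Pathway coverage of metabolites shared across two tissue regions.

Takes a handful of annotated ion masses, converts them to neutral
monoisotopic masses, and maps them onto the bundled pathway tables at
2 ppm to compute per-pathway coverage.
"""

import numpy as np

import orbimet as om
from orbimet.pathways import load_pathways, map_to_pathways

compounds = {c.name: c for c in om.bundled_compound_table()}
names = ["tryptophan", "kynurenine", "serotonin", "indole-3-acetate", "picolinate"]
masses = np.array([compounds[n].monoisotopic_mass for n in names])

pathways = load_pathways(om.bundled_pathway_table())
for res in map_to_pathways(masses, pathways, tolerance_ppm=2.0):
    print(
        f"{res.name:<35} {len(res.matched_members):>2} matched members, "
        f"coverage {res.coverage:.2%}"
    )
# Coverage is the fraction of a pathway's member compounds matched by the
# query masses; querying tryptophan-pathway metabolites concentrates the
# coverage on tryptophan metabolism.
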