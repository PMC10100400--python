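"""Accurate-mass annotation of measured negative-mode ion m/z values.

Annotates a short list of observed ions against the bundled compound
library using the two negative-mode adduct types at 5 ppm.
"""

import numpy as np

import orbimet as om

observed = np.array([116.0506, 133.0154, 96.9696, 119.0362, 162.0419])
compounds = om.bundled_compound_table()
hits = om.annotate(observed, compounds, tolerance_ppm=5.0)

print(f"{'observed':>10} {'compound':<28} {'adduct':<12} {'theoretical':>12} {'ppm':>6}")
for h in hits:
    print(
        f"{h.feature_mz:>10.4f} {h.compound.name:<28} {h.adduct.name:<12} "
        f"{h.theoretical_mz:>12.5f} {h.ppm_error:>6.2f}"
    )
# Each row is a level-3 identification: the observed ion mass matches the
# theoretical adduct m/z within 5 ppm. Isobaric compounds yield multiple
# rows per ion (accurate mass alone cannot distinguish them).
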