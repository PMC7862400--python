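"""Core per-domain disorder metrics on a hand-made example.

A 120-residue protein carries one domain (residues 11-90). We compute the
domain's DSDR (percentage of disordered residues), its consecutive
disordered regions (CDRs: runs longer than 20 residues, or longer than 40%
of the domain for domains of at most 50 residues), its grade on the 0-3
normalized scale, and its quadrant in the DSDR x CDRN plane.
"""

import numpy as np

from iddtools import normalize_dsdr, region_metrics

calls = np.zeros(120, dtype=bool)
calls[29:55] = True   # one 26-residue disordered run inside the domain
calls[70:80] = True   # a second, 10-residue run (too short to be a CDR)

m = region_metrics(calls, start=10, end=90)  # 0-based half-open = residues 11-90

print(f"domain length          : {m.length}")
print(f"DSDR                   : {m.dsdr:.2f} %")
print(f"CDR intervals          : {m.cdr_intervals}")
print(f"CDRN                   : {m.cdrn}")
print(f"DSDR grade             : {m.dsdr_grade}")
print(f"quadrant               : {m.quadrant}")
print(f"is IDD                 : {m.is_idd}")
print(f"normalized DSDR        : {normalize_dsdr(m.dsdr):.4f}  (0-3 scale)")
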