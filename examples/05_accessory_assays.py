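"""Accessory computations: Cks1 priming geometry, reporter units, growth.

Enumerates which TAD phosphosite pairs satisfy the Cks1 priming rule
(phosphothreonine 12-30 residues upstream of another CDK site), computes
beta-galactosidase reporter units from raw optical densities, and fits a
doubling time from a growth curve.
"""

import numpy as np

from phosphoscan import (
    PrimingRule,
    beta_gal_units,
    candidate_priming_pairs,
    doubling_time,
)
from phosphoscan.scheme import Site

# the five phosphosites of the Hcm1 TAD with printed residue numbers
sites = (
    Site("T428", 428, "T"), Site("T440", 440, "T"), Site("T447", 447, "T"),
    Site("T460", 460, "T"), Site("S471", 471, "S"),
)
pairs = candidate_priming_pairs(sites, PrimingRule())
print("candidate Cks1 priming pairs (primer -> target):")
for primer, target in pairs:
    spacing = int(target[1:]) - int(primer[1:])
    print(f"  {primer} -> {target}  (spacing {spacing} residues)")
print("note: T460 -> S471 is excluded (11 residues < 12), and S471 cannot")
print("prime because Cks1 binds phosphothreonine, not phosphoserine.\n")

units = beta_gal_units(od405=0.5, od600=1.0, volume_ml=1.0, minutes=100)
print(f"beta-galactosidase activity for OD405=0.5, OD600=1.0, 1 mL, "
      f"100 min: {units:.1f} units")

t = np.arange(0, 33, 1 / 3)  # plate reader: every 20 min for 33 h
od = 0.01 * 2 ** (t / 2.4)   # a culture doubling every 2.4 h
td = doubling_time(t, od, window=(0.2, 0.5))
print(f"doubling time fit inside OD 0.2-0.5: {td:.2f} h")
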