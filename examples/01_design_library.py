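"""Design a combinatorial phosphosite library and its mutagenic oligos.

Enumerates the 256-member A/E library over the 8 CDK sites of the Hcm1
TAD, plans a 6-oligo tiling of the 270-bp region with 21-27 bp overlaps,
and verifies that overlap-extension assembly of the oligo pool regenerates
exactly the enumerated library.
"""

import math

from phosphoscan import enumerate_assembly_products, enumerate_library, tile_region
from phosphoscan.hcm1 import ae_library, synthetic_tad_region

lib = ae_library()
genotypes = enumerate_library(lib)
print(f"A/E library: {len(genotypes)} genotypes "
      f"({lib.scheme.n_sites} sites x {{A,E}}), e.g. {genotypes[0]} ... "
      f"{genotypes[-1]}")

region = synthetic_tad_region()
plan = tile_region(region, lib, n_tiles=6, overlap_range=(21, 27))
print(f"\nTiling of the {len(region)}-bp region into {plan.n_tiles} oligos:")
for i, (start, end) in enumerate(plan.tiles):
    sites = ", ".join(lib.scheme.sites[k].label for k in plan.tile_sites[i])
    print(f"  tile {i + 1}: bases {start:>3}-{end:>3}, "
          f"{len(plan.variants[i]):>2} variants  [{sites or 'no sites'}]")
print(f"  overlaps between consecutive tiles: {plan.overlaps} bp")

result = enumerate_assembly_products(plan)
print(f"\nAssembly products: {len(result.products)} "
      f"(= {' x '.join(map(str, plan.variant_counts))} "
      f"= {math.prod(plan.variant_counts)}), "
      f"{result.n_impossible} impossible combinations")
print("Products reproduce the enumerated library:",
      set(result.products) == set(genotypes))
# Each oligo variant carries one state combination of the sites it covers;
# because overlaps never contain a phosphosite codon, any variant of one
# tile anneals to any variant of the next, so the pool assembles the full
# Cartesian product of per-site states.
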