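"""Contact-density signatures of an ideal helix and an extended strand.

Builds two noise-free synthetic chains, scans the contact cutoff over the
default 0–30 Å grid, and prints where the density mass sits.  Helical
chains put extra mass in the 5–7 Å window (one-turn i,i+4 contacts);
strands concentrate near 6.6–7 Å (i,i+2) instead.  Both share the ~3.8 Å
consecutive-Cα peak.
"""

import numpy as np

from csmkit import CutoffGrid, GeometryFamily, cumulative_contact_vector, make_chain, to_density

grid = CutoffGrid()
print(f"cutoff grid: {grid.d_min}-{grid.d_max} Å, step {grid.step} Å "
      f"-> {grid.n_thresholds} thresholds")

for kind in ("ideal_helix", "extended_strand"):
    chain = make_chain(GeometryFamily(kind, length=40))
    vector = cumulative_contact_vector(chain, grid)
    dens = to_density(vector, normalize=True)
    top = np.argsort(dens)[::-1][:4]
    peaks = ", ".join(
        f"{grid.thresholds[i]:.1f} Å ({dens[i]:.3f})" for i in sorted(top)
    )
    in_window = dens[(grid.thresholds >= 5.0) & (grid.thresholds <= 7.0)].sum()
    print(f"\n{kind} (40 residues, {vector.total_pairs} pairs)")
    print(f"  largest density bins: {peaks}")
    print(f"  density mass in 5-7 Å window: {in_window:.3f}")

print("\nEach bin value is the fraction of residue pairs whose distance "
      "first falls under that cutoff; the 5-7 Å mass separates helical "
      "from extended geometry.")
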