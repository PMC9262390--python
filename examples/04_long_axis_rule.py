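"""Test the long-axis (Hertwig's) rule on a synthetic cohort.

Fits moment-equivalent ellipses to interphase contours and correlates the
long-axis angle with the final division angle.  In the generator, as in
force-oriented mitotic domains, division orientation follows the polarity
crescent, not interphase cell shape — so the correlation is expected to be
absent, while the crescent-division coupling is strong.
"""

import numpy as np

from mitopolar import _angles, division, shape, stats, synthgen

config = synthgen.SyntheticDomainConfig(n_cells_per_side=15, image_size=384, seed=4)
geometry, truth = synthgen.generate_domain(config)

fits = [shape.fit_ellipse(c) for c in geometry.interphase]
records = [
    division.DivisionRecord(
        cell_id=row.cell_id, embryo_id=row.embryo_id, domain_id="MD1",
        side=row.side, final_signed_angle=row.true_final_division_angle_signed,
        folded_angle=abs(row.true_final_division_angle_signed),
        rotation_direction=row.true_rotation_direction,
        total_rotation=row.true_total_rotation,
    )
    for row in truth.itertuples(index=False)
]

res = shape.long_axis_rule_test(fits, records)
print(f"long-axis rule, n = {res.n} cells (folded angles):")
print(f"  Spearman rho = {res.folded_spearman.spearman_rho:+.3f}, "
      f"p = {res.folded_spearman.p_two_sided:.3f}   (no correlation expected)")

coupling = stats.spearman(
    _angles.wrap_axial(truth.true_crescent_angle.to_numpy()),
    truth.true_final_division_angle_signed.to_numpy(),
)
r2 = stats.pearson_r2(
    _angles.wrap_axial(truth.true_crescent_angle.to_numpy()),
    truth.true_final_division_angle_signed.to_numpy(),
)
print(f"crescent-division coupling: Spearman rho = {coupling.spearman_rho:+.3f}, "
      f"p = {coupling.p_two_sided:.2g}, R^2 = {r2.r_squared:.2f}")
print("division orientation follows the polarity crescent, not cell shape")
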