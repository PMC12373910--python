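"""Measure adsorption efficiency and dose a screen to a target MOI.

Simulates a liquid killing assay in dilute culture where only ~1 in 26
added phages productively infects (adsorption factor k = 26), converts
surviving fractions to apparent MOI through the Poisson zero class,
fits the origin-constrained line MOI_a = m * MOI_e, and uses the fold
reduction 1/m to plan the lysate volume for a screen targeting an
apparent MOI of 100.
"""

import phagescreen as ps

assay = ps.simulate.simulate_moi_assay(
    k=26.0, moie_grid=[float(m) for m in range(1, 11)], n_cells=10**6, seed=5
)
fit = ps.fit_adsorption(assay)
print(fit.points[["moie", "survival_fraction", "moia"]].round(4).to_string(index=False))
print(f"\nslope m = {fit.slope:.5f}; fold reduction 1/m = {fit.fold_reduction:.2f}")
print("i.e. the apparent MOI is ~26x lower than the phage:cell ratio added,")
print("so adsorption, not phage number, limits infection in this assay.")

volume = ps.plan_inoculum(
    target_moia=100.0,
    fold_reduction=fit.fold_reduction,
    cfu_per_ml=1e8,
    titer_pfu_per_ml=1e11,
    culture_volume_ml=1.0,
)
print(f"\nto reach apparent MOI 100 in 1 ml of 1e8 cfu/ml culture with a")
print(f"1e11 pfu/ml lysate, add {volume:.2f} ml of lysate (expected MOI "
      f"{100 * fit.fold_reduction:.0f}).")
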