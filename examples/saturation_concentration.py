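"""In-vivo apparent saturation concentration from single-cell photometry.

Renders two cell populations — below and above the phase boundary — and
runs the full measurement chain: segmentation, spherocylinder volume,
brightest-five-frame photometry, copy number and concentration, then a
Welch t test between focus and no-focus cells.  The pair of class means
brackets the apparent saturation concentration c_sat.
"""

import pandas as pd

from condenscan import cells, photometry, simkit

PPM = simkit.PHOTON_GAMMA_SHAPE * simkit.PHOTON_GAMMA_SCALE  # photons/molecule/frame

rows = []
for conc, has_focus, seed in ((92.0, False, 1), (113.0, True, 2)):
    pop = simkit.simulate_cell_population(
        60, rng=seed, concentration_uM=conc, n_frames=6,
        focus_fraction=1.0 if has_focus else 0.0,
        focus_excess_molecules=20000 if has_focus else 0)
    cal = photometry.CameraCalibration(bias=pop.camera.bias_counts,
                                       conversion_gain=1.40)
    for stack, truth in zip(pop.stacks, pop.truth.itertuples()):
        seg = cells.segment_cells(stack.data[0], stack.pixel_size)
        if seg.n_cells != 1:
            continue
        volume = cells.cell_volume_from_mask(seg, 1)
        photons = photometry.measure_cell_photons(stack.data, seg.labels == 1,
                                                  cal, 0.0)
        est = photometry.estimate_concentration(photons, PPM, volume,
                                                has_focus=has_focus)
        rows.append({"concentration_uM": est.concentration_uM,
                     "has_focus": has_focus})

df = pd.DataFrame(rows)
res = photometry.compare_populations(df, sample_size=100, seed=0)
print(f"no focus: {res.mean_no_focus:.1f} +/- {res.sd_no_focus:.1f} uM "
      f"(n = {res.n_no_focus})")
print(f"focus:    {res.mean_focus:.1f} +/- {res.sd_focus:.1f} uM "
      f"(n = {res.n_focus})")
print(f"Welch t = {res.t_statistic:.2f}, p = {res.p_value:.2e}")
lo, hi = res.csat_bracket
print(f"apparent c_sat lies between {lo:.0f} and {hi:.0f} uM: cells above it "
      "have a dense-phase focus, cells below stay homogeneous")
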