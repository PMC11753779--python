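"""Synthesise an ROI BOLD run with known effects and recover them by GLM.

The subthalamic nucleus is given condition amplitudes GO 0.5 / FS 1.5 /
SS 0.7 (signal units); the run adds drift and AR(1) noise.  The first-level
model (double-gamma HRF + temporal derivative, 1/128 Hz high-pass, AR(1)
prewhitening) estimates the amplitudes and the three standard contrasts.
"""

from sstpipe import (NoiseSpec, RaceParams, build_design_matrix, fit_run_glm,
                     get_design, simulate_session, split_runs, synthesize_run)
from sstpipe.bold import default_roi_roster

design = get_design("deHollander_7T")
events = split_runs(simulate_session(design, RaceParams(), seed=3),
                    design.n_runs)[0]
roster = default_roi_roster(
    {"STN": {"GO": (0.5, 0.0), "FS": (1.5, 0.0), "SS": (0.7, 0.0)}},
    n_voxels=8, seed=0)
stn_left = next(r for r in roster if r.key == "STN-l")

noise = NoiseSpec(sigma=1.0, ar1_phi=0.3, drift_amp=2.0, drift_period_s=300)
run = synthesize_run(design, [stn_left], noise, events, seed=4)
dm = build_design_matrix(events, design, run.roi_timeseries.shape[0],
                         confounds=run.confounds)
fit = fit_run_glm(run.roi_timeseries["STN-l"].to_numpy(), dm)

betas = dict(zip(fit.labels, fit.beta))
print(f"estimated AR(1) phi: {fit.ar1_phi:.2f} (true 0.30)")
for cond, truth in (("GO", 0.5), ("FS", 1.5), ("SS", 0.7)):
    print(f"beta[{cond}] = {betas[cond]:5.2f}   (true {truth})")
for name, (cope, varcope, z) in fit.contrasts.items():
    print(f"{name}: cope = {cope:5.2f}, z = {z:6.2f}")
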