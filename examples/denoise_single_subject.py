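"""Denoise one synthetic subject two ways and compare residual motion.

Simulates a high-motion subject, applies minimal preprocessing, then runs
the motion-parameter pipeline (24 regressors) and the tissue-mean pipeline
(WM + CSF + global signal, 3 regressors).  The FD-DVARS correlation — how
strongly frame-to-frame image changes track head motion — should collapse
after motion-parameter regression, at a much higher cost in temporal
degrees of freedom.
"""

from denoisebench import PreprocConfig, apply_pipeline, get_pipeline
from denoisebench.metrics import dvars, fd_dvars_metric, framewise_displacement
from denoisebench.synthcohort import CohortParams, make_phantom, simulate_subject
from denoisebench.workbench import prepare_subject

params = CohortParams()
tissue, parc = make_phantom(params.grid, params.n_rois, seed=0)
bold, motion = simulate_subject(tissue, parc, params.grid, "high", seed=11, params=params)
subject = prepare_subject("sub-001", bold, tissue, motion, PreprocConfig(), seed=11)

fd = framewise_displacement(motion)
print(f"mean FD = {fd.mean():.3f} mm")
print(f"{'pipeline':<16} {'FD-DVARS r':>10} {'tDOF lost':>10}")
for pid in ("baseline", "mp24", "wm+csf+gs"):
    res = apply_pipeline(subject, get_pipeline(pid))
    r = fd_dvars_metric(fd, dvars(res.vol))
    print(f"{pid:<16} {r:>10.3f} {res.tdof_used / bold.n_volumes:>9.1%}")
print("lower |r| = less residual motion; mp24 buys it with 12% of the tDOF")
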