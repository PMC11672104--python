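"""Trajectory dynamics metrics on a synthetic wild-type troponin run.

Generates a 5 x 3750-frame bundle with the wild-type apo statistics
(helix A/B angle ~ N(101.81, 9.15) deg, hinge ~ N(121.61, 7.24) deg,
interdomain distance ~ N(30.18, 1.34) A), re-measures every metric and
prints the pooled distribution summary.  The printed mean should sit
within sampling error of the planted value, the FWHM near
2*sqrt(2 ln 2)*sigma, and '% > 110 deg' is the fraction of frames with
the N-lobe hydrophobic patch in the open state.
"""

import numpy as np

from tncoupling.diststats import summarize
from tncoupling.geometry import ab_angle_series, hinge_angle_series
from tncoupling.synthetic import TrajectorySpec, gen_trajectory

bundle = gen_trajectory(TrajectorySpec(seed=1))
topo, regions = bundle.topology, bundle.regions

ab = np.concatenate([
    ab_angle_series(t, topo, regions["helix_a"], regions["helix_b"]).values
    for t in bundle.runs
])
hinge = np.concatenate([
    hinge_angle_series(t, topo, regions["nc_lobe"], regions["itc_domain"], regions["pivot"]).values
    for t in bundle.runs
])

s_ab = summarize(ab, threshold=110.0)
s_h = summarize(hinge)
print(f"A/B helix angle : mean {s_ab.mean:6.2f} deg  std {s_ab.std:5.2f}  "
      f"FWHM {s_ab.fwhm:5.2f}  % > 110 deg {s_ab.pct_above:4.1f}  (n={s_ab.n_samples})")
print(f"hinge angle     : mean {s_h.mean:6.2f} deg  std {s_h.std:5.2f}  FWHM {s_h.fwhm:5.2f}")
print("The A/B mean tracks opening of the TnC hydrophobic patch; a drop of")
print("~5.7 deg on phosphorylation is the wild-type response this package classifies.")
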