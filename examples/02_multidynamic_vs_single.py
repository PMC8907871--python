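"""The core multi-dynamic effect: MAGE vs SAGE when mean activity and FC
fluctuate on independent time courses.

The ground truth drives the mean states and the correlation states with
two independent semi-Markov chains (gamma lifetimes).  The single-dynamic
model (SAGE) has to compromise on one shared time course, which smears
its FC estimate toward homogeneity; the multi-dynamic model (MAGE) tracks
the true FC fluctuations.
"""

import numpy as np

from magefc import SimSpec, fit, infer_timecourses, match_states, simulate_multidynamic
from magefc.model import compose_moments
from magefc.postprocess import instantaneous_fc
from magefc.reproduce import desk_config

spec = SimSpec(kind="multidynamic_hsmm", n_channels=8, n_timepoints=6_000,
               k_mean=5.0, k_corr=30.0, seed=11)
gt = simulate_multidynamic(spec)
print("ground truth: mean-state lifetimes ~ Gamma(k=5), "
      "FC-state lifetimes ~ Gamma(k=30), independent chains")

iu = np.triu_indices(8, k=1)
true_edges = compose_moments(gt.timecourses, gt.basis).corr[:, iu[0], iu[1]]

for variant in ("mage", "sage"):
    model = fit([gt.data], desk_config(variant, seed=11, n_epochs=100))
    tcs = infer_timecourses(model, gt.data)
    beta_r = match_states(tcs, gt.timecourses, course="beta").mean_correlation
    edges = instantaneous_fc(model, gt.data)[:, iu[0], iu[1]]
    L = min(len(edges), len(true_edges))
    edge_r = np.nanmedian([
        np.corrcoef(edges[:L, e], true_edges[:L, e])[0, 1]
        for e in range(edges.shape[1])
    ])
    print(f"{variant.upper()}: FC-state recovery r={beta_r:.3f}; "
          f"median edge variance {np.median(edges.var(axis=0)):.4f}; "
          f"median edge-trajectory correlation with truth {edge_r:.3f}")
print("expected ordering: MAGE recovers the FC dynamics better and shows "
      "larger (truer) edge variance; SAGE's instantaneous FC looks too static")
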