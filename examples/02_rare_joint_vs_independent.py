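"""Why fit samples jointly: a rare population that per-sample fits miss.

Uses the canned two-sample benchmark (two overlapping large populations
plus a tight 1% cluster) and compares the joint fit against fitting each
sample on its own with the same settings.
"""

import numpy as np

from flare import Hyperparameters, fig3_scenario, fit

data, truth = fig3_scenario(seed=3)
mu_rare = truth.sample_means[:, 2]  # true per-sample means of the 1% cluster


def detected(res, m, mu, radius=0.9, cap=0.05):
    st = res.state
    for k in range(st.n_components):
        if not res.presence[k, m]:
            continue
        if st.Nk[m, k] / st.r[m].shape[0] > cap:
            continue
        if np.linalg.norm(st.omega[m, k] - mu) <= radius:
            return True
    return False


hp = Hyperparameters(K=12)
joint = fit(data, hp, seed=1003, max_sweeps=120)
print("joint fit detections:",
      {data[m].sample_id: detected(joint, m, mu_rare[m]) for m in range(2)})

for m in range(2):
    alone = fit([data[m]], hp, seed=1003, max_sweeps=120)
    print(f"independent fit of {data[m].sample_id}: "
          f"rare cluster detected = {detected(alone, 0, mu_rare[m])}")

print("\nThe joint fit pools the rare cluster's ~40 events per sample through "
      "its shared prototype, so it keeps a component on the cluster in both "
      "samples; the independent fits usually absorb those events into the "
      "neighbouring large population.")
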