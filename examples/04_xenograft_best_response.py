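"""Xenograft trajectories: relative tumor-volume change and BestResponse.

Generates exponential-growth trajectories Vol_t = Vol_0 exp((g - e) t) for
drug pairs on xenograft models, converts them to relative changes
dVol_t = (Vol_t - Vol_0)/Vol_0, and reports BestResponse — the minimum change
at or after day 10.  Negative BestResponse means the tumor shrank.
"""

from pairview import FixtureSpec, best_response, gen_xenograft, fpkm_to_tpm
from pairview import gen_expression

spec = FixtureSpec(seed=2)
for traj in gen_xenograft(spec, n_models=2)[:4]:
    br = best_response(traj)
    trend = "shrinking" if br < 0 else "growing"
    days = ", ".join(f"{t}d:{dv:+.2f}" for t, dv in traj.points[::2])
    print(f"{traj.model_id} {traj.drug_a}+{traj.drug_b}: [{days}] "
          f"BestResponse {br:+.3f} ({trend})")

# expression for xenograft models arrives in FPKM; convert to TPM so every
# context column sums to one million
fpkm = gen_expression(spec, unit="FPKM", prefix="x")
tpm = fpkm_to_tpm(fpkm)
print("TPM column sums:", tpm.values.sum(axis=0).round(1).tolist())
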