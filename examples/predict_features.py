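"""Train the four structural-property predictors and score them.

Trains on a dozen generated families and evaluates on held-out families
from the same generator — the desk-scale version of profile-based
structural feature prediction.  Prints Q scores for secondary structure
and MAE / Pearson r for RSA, residue depth and Phi; on held-out data Q3
well above chance (1/3) and MAE well below the scale of the targets show
the networks learned profile->structure mappings, not the families.
"""

import numpy as np

from ompscan import TrainingConfig, generate_families, train_bundle
from ompscan.metrics import mae, pcc, q_scores

train_fams = generate_families(101, 12, length=60)
heldout = generate_families(202, 4, length=60)

config = TrainingConfig(
    seed=0,
    hidden={"SS": (20, 10), "RD": (14,), "Phi": (14,), "RSA": (14,)},
    stage2_hidden={"SS": (10,), "RD": (6,), "RSA": (6,)},
    epochs_stage1=25, epochs_stage2=15,
)
print("training the four predictors (SS, RSA, RD, Phi)...")
bundle = train_bundle(train_fams, config)

true_ss = pred_ss = ""
tracks = {k: ([], []) for k in ("rsa", "rd", "phi")}
for profile, truth in heldout:
    feats, ss_ri = bundle.predict_all(profile)
    true_ss += truth.ss3
    pred_ss += feats.ss3
    for k, t, p in (("rsa", truth.rsa, feats.rsa),
                    ("rd", truth.rd, feats.rd),
                    ("phi", truth.phi_norm, feats.phi_norm)):
        tracks[k][0].append(t)
        tracks[k][1].append(p)

for name, value in q_scores(true_ss, pred_ss).items():
    print(f"  {name:3s} = {value:.3f}")
for k, (t, p) in tracks.items():
    t, p = np.concatenate(t), np.concatenate(p)
    print(f"  {k:3s}: MAE = {mae(p, t):.3f}  Pcc = {pcc(p, t):.3f}")
print("(Q3 is the fraction of residues with the correct 3-state class; "
      "MAE is on the [0,1] normalized scales)")
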