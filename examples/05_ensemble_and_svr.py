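"""Independent-cohort evaluation: SVM ensemble and survival regression.

A random-subspace ensemble (each member a grid-tuned RBF-SVM on a random
transcript subset) classifies an independent test cohort by majority
vote; support-vector regression predicts disease-free survival time.
"""

from metasurv import (
    SimulationConfig,
    ensemble_train_predict,
    make_paperlike_pair,
    svr_fit_predict,
)

config = SimulationConfig(
    n_samples=50, n_transcripts=40, n_informative=5,
    n_non_distant=24, n_distant=26, effect_size=2.0, seed=5,
)
train, test, informative = make_paperlike_pair(config)

preds, acc, model = ensemble_train_predict(
    train, test, informative, n_members=10, member_size=3, seed=0
)
print(f"ensemble of {len(model.members)} SVMs on the planted marker set")
print(f"test accuracy: {100 * acc:.2f}% on {test.n_samples} held-out samples")

pred_months, mae, r = svr_fit_predict(train, informative)
print(f"SVR survival prediction: MAE = {mae:.2f} months, Pearson R = {r:.4f}")
print()
print("The ensemble's majority vote is more robust than any single member;")
print("the regression shows the same markers also carry survival-time")
print("information, not just the binary metastasis class.")
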