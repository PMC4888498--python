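"""Why the negative-partitioning ensemble matters on 1:3 imbalanced data.

Trains (a) a single random forest on the full imbalanced corpus and (b) the
partition ensemble (negatives split into N = floor(n_neg/n_pos) parts, one
balanced forest per part, probabilities averaged), both under 5-fold
cross-validation, and compares sensitivity / specificity balance.
"""

import aptapair as ap

corpus = ap.generate_corpus(ap.FixtureConfig(n_pos=40, n_neg=120, effect_size=0.5, seed=0))
X, _ = ap.build_feature_matrix(corpus.dataset, corpus.pssms, corpus.tracks)
y = corpus.dataset.labels
cfg = ap.RFConfig(n_trees=60)

single = ap.cross_validate(X, y, k=5, rf_config=cfg, seed=0, strategy="single").mean
ensemble = ap.cross_validate(X, y, k=5, rf_config=cfg, seed=0).mean

print(f"{'':>18s} {'Sn':>6s} {'Sp':>6s} {'Acc':>6s} {'MCC':>6s} {'J':>6s}")
for label, m in (("single forest", single), ("partition ensemble", ensemble)):
    r = m.rounded()
    print(f"{label:>18s} {r['sn']:6.3f} {r['sp']:6.3f} {r['acc']:6.3f} "
          f"{r['mcc']:6.3f} {r['youden']:6.3f}")
print("\nThe single forest rides the majority class: specificity near 1 but")
print("sensitivity collapses. The ensemble trades a little specificity for a")
print("balanced operating point and a higher Youden's index J = Sn + Sp - 1.")
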