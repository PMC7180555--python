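"""Seed a new context's learner from the most similar labeled source domains.

Three source subjects are available; one shares the target's distribution
and two are far shifted.  Clustering the target's unlabeled data and
matching cluster centres to per-source class centres by cosine similarity
recovers the matched source for every activity label.
"""

from comeal import Dictionary, FeatureInstance, RandomForestLearner, WorldConfig, generate_feature_world, initialize_learner

cfg = WorldConfig(n_subjects=4, n_locations=1, subject_shift_scale=0.0, seed=11)
world = generate_feature_world(cfg, q=8, n_per_class=60)
related = []
for idx, subj in enumerate(cfg.subjects()[:-1]):
    src = world[(subj, "loc1")]
    if idx > 0:  # shift two sources far away from the target distribution
        src = Dictionary(
            [FeatureInstance(features=i.features + 30.0 * idx, label=i.label,
                             subject_id=i.subject_id, uid=i.uid) for i in src],
            role="related_labeled", domain_id=src.domain_id)
    related.append(src)

target = world[(cfg.subjects()[-1], "loc1")]
X_U = Dictionary([FeatureInstance(features=i.features, uid=i.uid) for i in target],
                 role="target_unlabeled")

db_l, report = initialize_learner(related, X_U, cfg.label_set, seed=0)
print(report.rows.to_string(index=False))
print(f"\ntransfer pool DB_L: {len(db_l)} instances")

model = RandomForestLearner(seed=0).fit(db_l)
print(f"initial accuracy on the target (hidden truth): {model.accuracy(target):.3f}")
# Every label selects the unshifted source (cosine similarity ~1), so the
# learner starts from data that actually matches the new context.
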