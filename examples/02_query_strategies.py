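"""Score unlabeled instances by informativeness and pick a query batch.

Trains the random-forest learner on one subject and ranks another
(shifted) subject's unlabeled data by posterior entropy: high-entropy
instances sit near class boundaries and are the most valuable to query.
"""

import numpy as np

from comeal import (
    RandomForestLearner,
    WorldConfig,
    entropy_informativeness,
    generate_feature_world,
    get_informative_instances,
)

cfg = WorldConfig(n_subjects=2, n_locations=1, subject_shift_scale=0.5, seed=7)
world = generate_feature_world(cfg, q=8, n_per_class=80)
model = RandomForestLearner(seed=0).fit(world[("S1", "loc1")])

target = world[("S2", "loc1")].copy(role="related_labeled")
posteriors = model.predict_posterior(target.X)
entropies = [entropy_informativeness(p) for p in posteriors]
print(f"entropy over {len(target)} target instances: "
      f"min {min(entropies):.3f}, max {max(entropies):.3f} (ln 4 = {np.log(4):.3f})")

batch = get_informative_instances(10, target, model, strategy="entropy")
batch_h = [entropy_informativeness(model.predict_posterior(i.features[None, :])[0])
           for i in batch]
print(f"top-10 query batch entropies: {np.round(batch_h, 3)}")
# The batch collects the instances the model is least sure about; labeling
# exactly these gives the largest accuracy gain per annotation spent.
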