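"""Train the synergy classifier on a synthetic fixture and evaluate it.

Generates a small drug-combination screen with a planted two-factor rule
(drug A broadly active AND drug B targeting an over-expressed gene), trains
the full projector/augmentor/aggregator pipeline at desk scale, and prints
held-out metrics.  Expect a balanced accuracy well above chance (~0.85+ with
the default conditions; chance is 0.5).
"""

from pairview import (FixtureSpec, SplitSpec, classification_metrics,
                      gen_drugs, gen_expression, gen_networks, gen_triplets,
                      make_splits, train)
from pairview.model import DrugCombinationModel
from pairview.recovery import desk_scale_config

spec = FixtureSpec(seed=1)
drugs = gen_drugs(spec)
nets = gen_networks(spec)
expr = gen_expression(spec)
triplets = gen_triplets(spec, drugs, expr)
print(f"{len(drugs.records)} drugs, {len(triplets)} triplets, "
      f"{int(sum(t.label for t in triplets))} synergistic")

splits = make_splits(triplets, SplitSpec(mode="vanilla", seed=1))
train_set = [triplets[i] for i in splits.train]
test_set = [triplets[i] for i in splits.test]

cfg = desk_scale_config(seed=1, steps=400)  # short demo run
model = DrugCombinationModel(drugs.records, cfg, nets.ppi,
                             ontology=nets.ontology, expression=expr)
history = train(model, train_set, cfg)
print(f"loss: {history[0].total:.3f} -> {history[-1].total:.3f} "
      f"over {len(history)} steps")

m = classification_metrics([t.label for t in test_set],
                           model.predict(test_set))
print("held-out:", {k: round(v, 3) for k, v in m.items()})
# bacc = balanced accuracy (mean of sensitivity and specificity at p>=0.5)
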