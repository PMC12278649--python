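"""Synthetic-dosage-lethality (SDL) pathway mining from confident predictions.

Novel (unscreened) triplets are enumerated, high-confidence synergy
predictions are turned into (over-expressed gene, drug-target gene) pairs,
and the pairs are filtered against an SDL network — over-activity of the
first gene makes the second essential, so a drug hitting the second is
selectively lethal in that context.
"""

from pairview import (FixtureSpec, build_gene_pairs,
                      enumerate_candidate_triplets, filter_sdl, gen_drugs,
                      gen_expression, gen_networks)
from pairview.data import ModalityId
from pairview.encoders import overexpressed_genes

spec = FixtureSpec(seed=3)
drugs = gen_drugs(spec)
nets = gen_networks(spec)
expr = gen_expression(spec)

drug_ids = [d.drug_id for d in drugs.records]
contexts = list(expr.values.columns)
ordered, novel = enumerate_candidate_triplets(drug_ids, contexts, observed=[])
print(f"candidate space: {ordered} ordered triplets, "
      f"{len(novel)} novel unordered ones")

# stand-in confident predictions for the first few novel triplets
predicted = [(t, 0.95) for t in novel[:40]]
targets = {d.drug_id: d.payloads.get(ModalityId.TARGET, frozenset())
           for d in drugs.records}
over = {c: overexpressed_genes(expr.values[c], spec.th_overexpressed)
        for c in contexts}
pairs = build_gene_pairs(predicted, 0.9, targets, over)
print(f"{len(pairs.pairs)} candidate gene pairs "
      f"(overactive context gene, essential drug target)")

result = filter_sdl(pairs, nets.sdl_pairs)
print(f"{len(result.pairs)} pairs survive the SDL filter, "
      f"covering {len(result.genes)} genes")
for (g_over, g_ess) in sorted(result.pairs)[:5]:
    print(f"  {g_over} overactive -> {g_ess} essential "
          f"(support {result.support[(g_over, g_ess)]})")
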