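"""Mine pairwise rules from a synthetic semantic-predication store.

Predications are subject-predicate-object triples; each becomes the
two-term transaction {subject, object}. A pair planted k times among n
otherwise-unique records has lift n*k/(k*k) = n/k, so the three planted
pairs (repeat counts 3, 4, 5 in a 60-record store) have lifts 20, 15, 12.
Selection keeps rules with lift > 1 and then above the mean lift; the
lifestyle filter keeps rules with at least one term of a focus semantic
type (individual behavior, finding, food, ...).
"""

from ckdrules.litmine import (
    default_semantic_filter,
    filter_predications,
    lifestyle_filter,
    mine_pair_rules,
    predications_to_transactions,
)
from ckdrules.synthetic import default_predication_spec, generate_predications

records = generate_predications(default_predication_spec(n=60), seed=1)
cfg = default_semantic_filter()
filtered = filter_predications(records, cfg)
t = predications_to_transactions(filtered)
rules, report = mine_pair_rules(t, min_count=2)

print(f"{len(records)} predications -> {t.n} pair transactions over "
      f"{len(t.catalog)} terms")
print(f"count >= 2 and lift > 1: {report.n_after_stage1} rules; "
      f"mean lift {report.mean_lift:.2f} -> {report.n_final} final")
for r in rules:
    print(f"  {r.rule_str()}  lift={r.lift:.2f} count={r.count}")

semtypes = {}
for r in records:
    semtypes[r.subject] = r.subject_semtype
    semtypes[r.object] = r.object_semtype
lifestyle, keywords = lifestyle_filter(rules, cfg, semtypes)
print(f"\nlifestyle-focused rules: {[r.rule_str() for r in lifestyle]}")
print(f"lifestyle keyword list: {keywords}")
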