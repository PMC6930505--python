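"""Mine a five-transaction toy database and inspect the rule metrics.

Shows the three interestingness measures on a database small enough to
count by hand, and checks the level-wise miner against exhaustive
enumeration.
"""

from ckdrules import (
    MiningParams,
    TransactionSet,
    apriori_mine,
    brute_force_oracle,
    generate_rules,
    rule_metrics,
)

t = TransactionSet([{"a", "b"}, {"a", "b", "c"}, {"a", "c"}, {"b"}, {"a", "b"}])

r = rule_metrics({"c"}, {"a"}, t)
print(f"{r.rule_str()}: support={r.support} confidence={r.confidence} lift={r.lift}")
# every transaction containing c also contains a -> confidence 1;
# lift 1.25 > 1 means c and a co-occur more than independence predicts

params = MiningParams(min_support=0.4, max_len=3)
frequent = apriori_mine(t, params)
assert frequent == brute_force_oracle(t, 0.4, max_len=3)
print(f"\nfrequent itemsets at minSup=0.4 ({len(frequent)}):")
for s in frequent:
    print(f"  {{{','.join(s.items)}}}  support={s.support:.1f} count={s.count}")

rules = generate_rules(frequent, t, MiningParams(0.4, min_confidence=0.7))
print(f"\nrules with confidence >= 0.7 ({len(rules)}):")
for r in rules:
    print(f"  {r.rule_str()}  conf={r.confidence:.2f} lift={r.lift:.4f}")
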