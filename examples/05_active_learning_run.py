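"""Full collaborative active-learning run on the context-change scenario.

A new subject arrives; the learner is seeded from the other subjects,
then queries the expert pool for 15% of the unlabeled stream.  Compares
the collaborative variant (CAL) with random querying (RAL) and with
collaboration disabled (NCAL).
"""

from comeal import RunConfig, WorldConfig, build_scenario, run_driver

for variant in ("CAL", "RAL", "NCAL"):
    data = build_scenario("context_change", WorldConfig(seed=5), seed=5)
    cfg = RunConfig(variant=variant, K=10, u_th=0.2, budget_fraction=0.15, seed=5)
    r = run_driver(data.related, data.X_L, data.X_U, data.label_set,
                   data.pool, cfg, data.eval_pool)
    trace = " -> ".join(f"{a:.3f}" for a in r.accuracy_trace())
    print(f"{variant:5s} accuracy {trace}")
    print(f"      cost {r.ledger.total_cost:7.2f}  "
          f"perfect-expert queries {r.queries_of_kind('perfect'):2d}  "
          f"per-expert {r.ledger.query_counts()}")
# CAL broadcasts each round's labels to the updatable experts, so cheap
# experts gain confidence and absorb queries the expensive near-perfect
# annotator would otherwise receive (compare the perfect-expert counts).
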