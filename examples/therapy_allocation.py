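"""Therapy-allocation check: does expression confirm the IHC-based decision?

Simulates ER and PGR cohorts with IHC label noise, makes three-state
expression calls, assigns each patient to one of four concordance groups
(hormone-positive confirmed / negative confirmed / positive contradicted /
negative contradicted) and estimates relapse-free survival per group with
Greenwood 95% bands.
"""

import numpy as np

import receptorcall as rc

n = 1500
er_cfg = rc.with_options(rc.preset("ER", "ExMax"), n_samples=n, seed=11,
                         ihc_error_rate=0.05)
pgr_cfg = rc.with_options(rc.preset("PGR", "ExMax"), n_samples=n, seed=12,
                          ihc_error_rate=0.08)
er_expr, er_ihc, _ = rc.simulate_cohort(er_cfg)
pgr_expr, pgr_ihc, _ = rc.simulate_cohort(pgr_cfg)

groups = []
for rec_cfg, expr in ((er_cfg, er_expr), (pgr_cfg, pgr_expr)):
    model = rc.fit_exmax(expr)
    domain = rc.critical_domain(model, alpha=0.05)
    groups.append(rc.call_cohort(model, domain, expr.values))
er_calls, pgr_calls = groups

assigned = [rc.assign_group(ei, pi, ec, pc)
            for ei, pi, ec, pc in zip(er_ihc, pgr_ihc, er_calls, pgr_calls)]
for g in rc.AllocationGroup:
    print(f"group {g.value} ({g.name.lower().replace('_', ' ')}): "
          f"{sum(a is g for a in assigned)} patients")
print(f"unassigned: {sum(a is None for a in assigned)}")

# synthetic follow-up: contradicted groups relapse faster
rng = np.random.default_rng(13)
records = []
for a in assigned:
    hazard = 0.02 if a in (rc.AllocationGroup.POSITIVE_CONTRADICTED,
                           rc.AllocationGroup.NEGATIVE_CONTRADICTED) else 0.008
    t = rng.exponential(1 / hazard)
    records.append(rc.SurvivalRecord(min(t, 120.0), t < 120.0))

curves = rc.group_survival(assigned, records)
for g, c in curves.items():
    print(f"group {g.value}: S(60 months) = {c.at(60):.2f}")

print("\nContradicted groups flag patients whose systemic-therapy choice,")
print("based on IHC alone, the expression data call into question.")
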