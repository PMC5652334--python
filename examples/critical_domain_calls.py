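"""Three-state receptor calls with an abstaining critical domain.

Uses the published ER mixture parameters to build the responsibility
functions, derives the critical domain at alpha = 0.05, and calls a few
expression values.  Values inside the domain are 'GE0': neither component
explains them with 95% posterior probability, so no decision is made.
"""

import receptorcall as rc

model = rc.preset("ER", "ExMax").model
cp = rc.bayes_cutpoint(model)
domain = rc.critical_domain(model, alpha=0.05)

print(f"ER model: mu- = {model.neg.mu}, mu+ = {model.pos.mu}, pi+ = {model.weight_pos}")
print(f"cut-point (responsibility 0.5):    {cp.threshold:.3f}")
print(f"critical domain (alpha = 0.05):    [{domain.x_lower:.3f}, {domain.x_upper:.3f}]")

for x in [7.5, 8.6, 9.4, 10.2, 11.5]:
    call = rc.call_sample(model, domain, x)
    print(f"  x = {x:5.2f}  ->  {call.state.value:4s}  (r- = {call.responsibility_neg:.3f})")

print("\nGE- / GE+ are confident calls; GE0 flags expression the mixture")
print("cannot attribute to either receptor state at the 95% level.")
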