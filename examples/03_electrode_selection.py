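"""Prune the electrode array with greedy wrapper selection.

Uses the selection benchmark world: four electrodes (Au, Ag, Cu, CuO2)
each resolve one cross-treatment class collision, and three (AgO2,
AgCl, Ag2CO3) carry no signal.  A Probabilistic Neural Network scored
by group cross-validation drives forward, backward and stepwise
searches.
"""

import sfamtongue as st

data = st.generate_dataset(st.selection_benchmark_config())
plan = st.make_group_kfold(data.groups, 4)
evaluator = st.make_pnn_evaluator(st.PNNParams(sigma=0.1))

results = {
    "Forward PNN": st.forward_select(data, evaluator, plan),
    "Backward PNN": st.backward_select(data, evaluator, plan, target_size=4),
    "Stepwise PNN": st.stepwise_select(data, evaluator, plan),
}

print(st.selection_report(results))
print("stepwise trace (subset -> CV rate):")
for subset, rate in results["Stepwise PNN"].trace:
    print(f"  {'/'.join(subset):24s} {rate:6.2f}%")

# Every accepted electrode raises the cross-validated rate; the search
# stops at the informative quartet because no fifth electrode helps and
# dropping any of the four merges two honey classes.
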