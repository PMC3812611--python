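"""Sweep (rho, beta) and pick the smallest model with the best rate.

An embedded SFAM pays memory per category: O weight rows of 2d floats
plus O mapfield labels.  The sweep trains one network per grid cell on
the training groups, scores it on held-out validation groups, and the
selector maximizes the recognition rate, then minimizes the mapfield.
"""

import sfamtongue as st

data = st.generate_dataset(st.separable_config(seed=7))
train, test = st.split_train_test(data)  # M1-M8 train, M9-M12 test

plan = st.make_group_kfold(train.groups, 4)  # order-4 CV: 24/8 per fold
cv = st.cross_validate_grid(train, st.GridSpec.coarse(), plan)

print(f"coarse sweep: {len(cv.folds)} folds x 9 rho values x 10 beta values")
print(
    f"best cell: rho={cv.best.rho:g} beta={cv.best.beta:g} "
    f"rate={cv.best.rate:.1f}% mapfield={cv.best.mapfield} (fold {cv.best.fold})"
)

# refine around the classic sweet spot at 0.05 steps
fold = cv.best.fold
val = list(plan.fold_groups[fold])
tr = [g for g in train.group_order if g not in val]
fine = st.grid_search(train, st.GridSpec.fine(), tr, val)
print("\nfine sweep (rho 0.1-0.3 x beta 0.7-0.8, step 0.05):")
print(fine.to_text())

# A 100% rate with mapfield 4 means one category per honey class — the
# minimal memory footprint a 4-class network can have.
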