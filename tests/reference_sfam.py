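"""Independent, naively written SFAM reference used as a test oracle.

Pure-Python lists and explicit loops throughout; deliberately shares no
code with the package.  Implements the same fixed algorithm variant:
min-max normalization with clipping (constant column -> 0), complement
coding, choice T = |I^w|/(alpha+|w|), vigilance |I^w|/|I| >= rho,
match tracking raising the working vigilance to match+epsilon within a
single pattern's search, new category w = I on exhaustion, learning
w' = beta*min(I,w) + (1-beta)*w, row-order presentation, stop on a
changeless epoch.
"""


def ref_scaler(X):
    d = len(X[0])
    mins = [min(row[i] for row in X) for i in range(d)]
    maxs = [max(row[i] for row in X) for i in range(d)]
    return mins, maxs


def ref_normalize(x, mins, maxs):
    out = []
    for i in range(len(x)):
        if maxs[i] == mins[i]:
            out.append(0.0)
        else:
            v = (x[i] - mins[i]) / (maxs[i] - mins[i])
            out.append(min(1.0, max(0.0, v)))
    return out


def ref_code(a):
    return list(a) + [1.0 - v for v in a]


def _norm1_min(I, w):
    s = 0.0
    for k in range(len(I)):
        s += I[k] if I[k] < w[k] else w[k]
    return s


def ref_train_pattern(weights, labels, I, label, beta, rho, alpha, eps):
    """Mutates weights/labels in place; returns True if anything changed."""
    if weights:
        acts = []
        for j, w in enumerate(weights):
            T = _norm1_min(I, w) / (alpha + sum(w))
            acts.append((-T, j))
        acts.sort()  # descending T, ties toward the lowest index
        rho_w = rho
        for _negT, j in acts:
            m = _norm1_min(I, weights[j]) / sum(I)
            if m < rho_w:
                continue
            if labels[j] == label:
                old = list(weights[j])
                new = [
                    beta * min(I[k], old[k]) + (1.0 - beta) * old[k]
                    for k in range(len(old))
                ]
                weights[j] = new
                return any(a != b for a, b in zip(old, new))
            rho_w = m + eps
    weights.append(list(I))
    labels.append(label)
    return True


def ref_fit(X, y, beta, rho, alpha=0.001, eps=0.001, max_epochs=100):
    mins, maxs = ref_scaler(X)
    coded = [ref_code(ref_normalize(x, mins, maxs)) for x in X]
    weights, labels = [], []
    for _ in range(max_epochs):
        changed = False
        for I, lab in zip(coded, y):
            if ref_train_pattern(weights, labels, I, lab, beta, rho, alpha, eps):
                changed = True
        if not changed:
            break
    return {"weights": weights, "labels": labels, "mins": mins, "maxs": maxs}


def ref_predict(model, x, alpha=0.001):
    I = ref_code(ref_normalize(x, model["mins"], model["maxs"]))
    best_T, best_j = None, None
    for j, w in enumerate(model["weights"]):
        T = _norm1_min(I, w) / (alpha + sum(w))
        if best_T is None or T > best_T:
            best_T, best_j = T, j
    return model["labels"][best_j]
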