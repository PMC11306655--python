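"""Independent reference computations used by the test suite only."""

import numpy as np
from sklearn.model_selection import StratifiedKFold

from pdfe import knn_predict


def brute_force_prefix_losses(X, y, ranked, ks, folds, seed, standardize=True):
    """Per-k CV misclassification of top-k prefixes, recomputed from
    scratch for each k with explicit fold loops and the standalone 1-NN
    predictor (no cumulative-distance shortcut)."""
    X = np.asarray(X, dtype=np.float64)
    losses = []
    for k in ks:
        cols = ranked[:k]
        errs = 0
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        for tr, te in skf.split(X, y):
            Xtr, Xte = X[tr][:, cols], X[te][:, cols]
            if standardize:
                mu, sd = Xtr.mean(0), Xtr.std(0)
                sd = np.where(sd == 0, np.inf, sd)
                Xtr, Xte = (Xtr - mu) / sd, (Xte - mu) / sd
            preds = knn_predict(Xtr, y[tr], Xte, k=1)
            errs += int((preds != y[te]).sum())
        losses.append(errs / len(y))
    return np.array(losses)
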