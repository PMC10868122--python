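"""End-to-end orchestration: encode -> scale -> train -> evaluate -> predict.

These functions are the programmatic core behind the command-line
interface.  They consume labeled FASTA (labels in headers as written by
:func:`m1apred.synthdata.write_fasta`), encode every valid window into the
522-value feature vector, train a named ensemble configuration, and emit
evaluation reports under either the independent 70/30 protocol or k-fold
cross-validation.  Invalid windows are skipped with a logged count rather
than aborting, so real-world FASTA inputs with stray records still run.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
import numpy as np

from m1apred import ensembles, evalstats, features, seqio, synthdata

logger = logging.getLogger("m1apred")


@dataclass(frozen=True)
class RunConfig:
    """Validated settings of one training run."""

    model: str = "boosting/hist_gradient_boost"
    W: int = 41
    hahn_u: float = 0.0
    hahn_v: float = 0.0
    protocol: str = "independent"  # or "kfold"
    k: int = 10
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self):
        if self.model not in ensembles.MODEL_REGISTRY:
            raise ensembles.ConfigurationError(f"unknown model {self.model!r}")
        if self.protocol not in ("independent", "kfold"):
            raise ValueError("protocol must be 'independent' or 'kfold'")
        if self.W % 2 == 0 or self.W < 1:
            raise ValueError("window length must be a positive odd integer")


def load_labeled_windows(fasta_path, W: int = 41) -> list[seqio.RnaWindow]:
    """Read a FASTA of labeled windows, skipping invalid records with a log line."""
    records = seqio.read_fasta(fasta_path)
    windows, skipped = [], 0
    for rid, seq in records:
        label = synthdata.parse_label(rid)
        try:
            windows.append(seqio.validate_window(seq, W, id=rid, label=label))
        except seqio.WindowError as exc:
            skipped += 1
            logger.debug("skipping %s: %s", rid, exc)
    if skipped:
        logger.warning("skipped %d invalid window(s) of %d records", skipped, len(records))
    if not windows:
        raise RuntimeError("no valid windows in input")
    return windows


def encode_windows(windows, u: float = 0.0, v: float = 0.0):
    """Feature matrix X (n x 522), labels y (or None), ids, and column names."""
    X = np.vstack([features.assemble(w, u=u, v=v).values for w in windows])
    lab_map = {"positive": 1, "negative": 0}
    if all(w.label in lab_map for w in windows):
        y = np.array([lab_map[w.label] for w in windows])
    else:
        y = None
    return X, y, [w.id for w in windows], features.feature_names()


def _evaluate(bundle, X_te, y_te, threshold: float) -> evalstats.EvaluationReport:
    scores = ensembles.predict_scores(bundle, X_te)
    y_pred = (scores >= threshold).astype(int)
    return evalstats.metrics(evalstats.confusion(y_te, y_pred), y_true=y_te, scores=scores)


def run_train(config: RunConfig, fasta_path, bundle_path=None):
    """Train the configured model on a labeled FASTA and evaluate it.

    Returns ``(bundle, reports)``: under the independent protocol a single
    held-out report; under k-fold, one report per fold plus a mean report
    under the key ``"mean"``.  The persisted bundle (when ``bundle_path``
    is given) is always trained on the full independent-protocol training
    partition or, for k-fold, on all data.
    """
    windows = load_labeled_windows(fasta_path, config.W)
    X, y, _, cols = encode_windows(windows, u=config.hahn_u, v=config.hahn_v)
    if y is None:
        raise RuntimeError("training requires labeled input (|label=pos / |label=neg headers)")
    spec = ensembles.ModelSpec.from_registry(config.model, seed=config.seed)
    logger.info("training %s on %d windows (%d features), protocol=%s, seed=%d",
                config.model, len(y), X.shape[1], config.protocol, config.seed)

    reports: dict[str, evalstats.EvaluationReport] = {}
    if config.protocol == "independent":
        plan = evalstats.split_70_30(len(y), y, seed=config.seed)
        bundle = ensembles.train(spec, X[plan.train], y[plan.train], columns=cols)
        reports["independent"] = _evaluate(bundle, X[plan.test], y[plan.test], config.threshold)
    else:
        plan = evalstats.kfold(len(y), k=config.k, seed=config.seed)
        fold_reports = []
        for f, (tr, te) in enumerate(plan.folds):
            fold_bundle = ensembles.train(spec, X[tr], y[tr], columns=cols)
            rep = _evaluate(fold_bundle, X[te], y[te], config.threshold)
            reports[f"fold{f + 1}"] = rep
            fold_reports.append(rep)
        mean_counts = evalstats.ConfusionCounts(
            TP=sum(r.counts.TP for r in fold_reports), TN=sum(r.counts.TN for r in fold_reports),
            FP=sum(r.counts.FP for r in fold_reports), FN=sum(r.counts.FN for r in fold_reports))
        reports["mean"] = evalstats.EvaluationReport(
            counts=mean_counts,
            Acc=float(np.mean([r.Acc for r in fold_reports])),
            Sp=float(np.mean([r.Sp for r in fold_reports])),
            Sn=float(np.mean([r.Sn for r in fold_reports])),
            MCC=float(np.mean([r.MCC for r in fold_reports])),
            F1=float(np.mean([r.F1 for r in fold_reports])),
            AUROC=float(np.mean([r.AUROC for r in fold_reports])))
        bundle = ensembles.train(spec, X, y, columns=cols)

    if bundle_path is not None:
        bundle.save(bundle_path)
        logger.info("bundle written to %s", bundle_path)
    return bundle, reports


def run_predict(bundle_path, fasta_path, W: int | None = None, threshold: float = 0.5,
                hahn_u: float = 0.0, hahn_v: float = 0.0) -> list[dict]:
    """Score every candidate adenosine site in each input sequence.

    Sequences of arbitrary length are scanned per-A with full flanks; each
    eligible site yields ``{sequence, position, score, call}`` with the call
    thresholded at 0.5 by default.
    """
    bundle = ensembles.ModelBundle.load(bundle_path)
    W = W or seqio.DEFAULT_WINDOW
    calls: list[dict] = []
    for rid, seq in seqio.read_fasta(fasta_path):
        sites = seqio.scan_sites(seq, W, id=rid)
        if not sites:
            logger.warning("no eligible A site in record %s", rid)
            continue
        X = np.vstack([features.assemble(w, u=hahn_u, v=hahn_v).values for _, w in sites])
        scores = ensembles.predict_scores(bundle, X)
        for (pos, _), s in zip(sites, scores):
            calls.append({"sequence": rid, "position": pos, "score": float(s),
                          "call": "m1A" if s >= threshold else "non-m1A"})
    return calls


def run_compare(config: RunConfig, fasta_path, model_names, trials: int = 10) -> list[dict]:
    """Pairwise statistical comparison of named models on a shared split.

    For every model pair the pooled two-proportion z test (on held-out
    accuracies), the resampled paired t-test (over repeated resplits) and
    McNemar's test (on the shared held-out set) are reported.
    """
    if len(model_names) < 2:
        raise ValueError("need at least two model names to compare")
    windows = load_labeled_windows(fasta_path, config.W)
    X, y, _, cols = encode_windows(windows, u=config.hahn_u, v=config.hahn_v)
    if y is None:
        raise RuntimeError("comparison requires labeled input")
    plan = evalstats.split_70_30(len(y), y, seed=config.seed)
    preds: dict[str, np.ndarray] = {}
    for name in model_names:
        spec = ensembles.ModelSpec.from_registry(name, seed=config.seed)
        bundle = ensembles.train(spec, X[plan.train], y[plan.train], columns=cols)
        preds[name] = ensembles.predict(bundle, X[plan.test])
    y_te = y[plan.test]

    def fit_predict_factory(name):
        def fp(X_tr, y_tr, X_te):
            spec = ensembles.ModelSpec.from_registry(name, seed=config.seed)
            b = ensembles.train(spec, X_tr, y_tr)
            return ensembles.predict(b, X_te)
        return fp

    rows = []
    for a, b in itertools.combinations(model_names, 2):
        correct_a, correct_b = preds[a] == y_te, preds[b] == y_te
        z, p_z = evalstats.z_two_proportion(int(correct_a.sum()), len(y_te),
                                            int(correct_b.sum()), len(y_te))
        disc_b = int((correct_a & ~correct_b).sum())
        disc_c = int((~correct_a & correct_b).sum())
        if disc_b + disc_c == 0:
            mc_stat, p_mc = 0.0, 1.0
        else:
            mc_stat, p_mc = evalstats.mcnemar(disc_b, disc_c)
        t, p_t = evalstats.resampled_paired_ttest(
            fit_predict_factory(a), fit_predict_factory(b), X, y, trials=trials, seed=config.seed)
        rows.append({"model_a": a, "model_b": b, "z": z, "p_z": p_z,
                     "t": t, "p_t": p_t, "mcnemar_stat": mc_stat, "p_mcnemar": p_mc})
    return rows
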