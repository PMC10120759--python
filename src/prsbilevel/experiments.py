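"""End-to-end method comparison on simulated replicates.

Wires the simulator, the samplers and the scoring machinery into the
study's evaluation protocol: fit each method from the replicate's summary
statistics, build (group-wise) scores on the test cohort, estimate
combination weights by 10-fold cross-validation on the test set, and report
the across-fold mean AUC (phenotype binarized at the top decile) and R^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .comparators import LDpredFunct, PerSnpHeritability, PRSCSAuto
from .datatypes import ValidationError
from .gibbs import BilevelShrinkagePRS
from .metrics import binarize_top_decile
from .scoring import GroupScoreCombiner, GroupScores, group_scores
from .simulate import StudyBundle, run_setting, true_per_snp_h2


@dataclass
class MethodResult:
    """Cross-validated performance of one method on one replicate."""

    method: str
    auc: float
    r2: float
    delta2_mean: np.ndarray | None = None


def cv_metrics(scores: GroupScores, y: np.ndarray, seed: int = 0,
               external: np.ndarray | None = None) -> tuple[float, float]:
    """Mean held-out AUC (top-decile cases, logistic weights) and R^2
    (quantitative weights) over 10 CV folds."""
    labels = binarize_top_decile(y)
    binary = GroupScoreCombiner(trait="binary", random_state=seed)
    binary.fit(scores, labels, external=external)
    aucs = [m["auc"] for m in binary.fold_metrics_ if "auc" in m]
    quant = GroupScoreCombiner(trait="quantitative", random_state=seed)
    quant.fit(scores, y, external=external)
    r2s = [m["r2"] for m in quant.fold_metrics_]
    return float(np.mean(aucs)), float(np.mean(r2s))


def evaluate_replicate(bundle: StudyBundle, methods=("bils", "prscs"),
                       seed: int = 0, gibbs_params: dict | None = None,
                       L: int = 40) -> dict[str, MethodResult]:
    """Fit and score the requested methods on one simulated replicate.

    Methods: "bils" (bilevel shrinkage with the replicate's annotations),
    "prscs" (single-group special case), "hybrid" (bilevel group scores plus
    the single-group PRS as an extra weighted column), "ldpredfunct"
    (closed-form functional prior with true per-SNP heritabilities, L bins).
    """
    gibbs_params = dict(gibbs_params or {})
    gibbs_params.setdefault("random_state", seed)
    out: dict[str, MethodResult] = {}
    need_bils = {"bils", "hybrid"} & set(methods)
    need_prscs = {"prscs", "hybrid"} & set(methods)

    bils = prscs = None
    if need_bils:
        bils = BilevelShrinkagePRS(**gibbs_params)
        bils.fit(bundle.sumstats, bundle.blocks, bundle.annotations)
    if need_prscs:
        prscs = PRSCSAuto(**gibbs_params)
        prscs.fit(bundle.sumstats, bundle.blocks)

    for method in methods:
        if method == "bils":
            scores = group_scores(bundle.G_test, bils.posterior_)
            a, r = cv_metrics(scores, bundle.y_test, seed=seed)
            out[method] = MethodResult(method, a, r, bils.delta2_mean_)
        elif method == "prscs":
            scores = group_scores(bundle.G_test, prscs.posterior_)
            a, r = cv_metrics(scores, bundle.y_test, seed=seed)
            out[method] = MethodResult(method, a, r, prscs.delta2_mean_)
        elif method == "hybrid":
            scores = group_scores(bundle.G_test, bils.posterior_)
            ext = prscs.predict(bundle.G_test)
            a, r = cv_metrics(scores, bundle.y_test, seed=seed, external=ext)
            out[method] = MethodResult(method, a, r)
        elif method == "ldpredfunct":
            if bundle.setting.overlap != "none":
                raise ValidationError(
                    "the functional-prior comparator assumes non-overlapping "
                    "annotations")
            h = PerSnpHeritability.from_total(
                true_per_snp_h2(bundle.setting, bundle.annotations,
                                bundle.variant_ids),
                bundle.setting.h2)
            model = LDpredFunct(L=L).fit(bundle.sumstats, bundle.blocks, h)
            scores = model.bin_scores(bundle.G_test)
            a, r = cv_metrics(scores, bundle.y_test, seed=seed)
            out[method] = MethodResult(method, a, r)
        else:
            raise ValidationError(f"unknown method {method!r}")
    return out


def compare_setting(setting_id: int, scale: float = 0.02,
                    n_replicates: int = 10, seed: int = 0,
                    methods=("bils", "prscs"),
                    gibbs_params: dict | None = None) -> dict:
    """Replicate-level comparison table for one simulation setting.

    Returns per-method AUC/R^2 arrays across replicates plus means and
    normal-approximation 95% intervals. Replicate r uses seed ``seed + r``
    for data generation and fitting.
    """
    results: dict[str, dict] = {m: {"auc": [], "r2": []} for m in methods}
    delta2: list[np.ndarray] = []
    for r in range(n_replicates):
        bundle = run_setting(setting_id, scale=scale, seed=seed + r)
        reps = evaluate_replicate(bundle, methods=methods, seed=seed + r,
                                  gibbs_params=gibbs_params)
        for m in methods:
            results[m]["auc"].append(reps[m].auc)
            results[m]["r2"].append(reps[m].r2)
        if "bils" in reps and reps["bils"].delta2_mean is not None:
            delta2.append(reps["bils"].delta2_mean)
    table = {}
    for m in methods:
        for metric in ("auc", "r2"):
            vals = np.array(results[m][metric])
            half = 1.96 * vals.std(ddof=1) / np.sqrt(len(vals)) \
                if len(vals) > 1 else 0.0
            table[m, metric] = {
                "values": vals,
                "mean": float(vals.mean()),
                "ci": (float(vals.mean() - half), float(vals.mean() + half)),
            }
    return {"table": table, "delta2_bils": np.array(delta2) if delta2 else None,
            "setting_id": setting_id, "scale": scale,
            "n_replicates": n_replicates, "seed": seed}
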