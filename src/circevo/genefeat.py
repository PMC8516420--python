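"""Exon/gene features and logistic models of circRNA parental genes.

Feature side: exon classes (circRNA-internal, parental-outside,
non-parental, UTR), per-class conservation medians, per-exon tissue
frequency from binned FPKM, GC amplitude across intron-exon boundaries
(last 250 intronic vs. first 50 exonic bases), isochore classes and the
Yanai tissue-specificity index tau.

Model side: binomial GLMs of parental-gene (or hotspot) status on
standardized gene features.  Predictor subsets are chosen by repeated
cross-validation on an 80% training split; the selected model's
standardized log-odds and p-values come from a maximum-likelihood fit,
and accuracy/sensitivity/specificity are evaluated on the held-out 20%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression

from circevo.evo import CircAnnotation
from circevo.formats import (
    ConservationTrack,
    GeneModel,
    GenomicInterval,
    merge_intervals,
)

ISOCHORE_CLASSES = ("L1", "L2", "H1", "H2", "H3")


def isochore_class(gc: float) -> str:
    """Isochore bin of a GC fraction; boundaries belong to the upper class
    (GC exactly 37% is L2, exactly 47% is H2)."""
    pct = 100.0 * gc
    if pct < 37.0:
        return "L1"
    if pct < 42.0:
        return "L2"
    if pct < 47.0:
        return "H1"
    if pct < 52.0:
        return "H2"
    return "H3"


def gc_content(seq: str) -> float:
    if not seq:
        return float("nan")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def tau(expression) -> float:
    """Yanai tissue-specificity index on per-tissue mean expression:
    0 = uniform, 1 = single-tissue."""
    x = np.asarray(list(expression), dtype=float)
    if x.size < 2:
        raise ValueError("tau requires at least two tissues")
    if np.any(x < 0):
        raise ValueError("expression must be non-negative")
    m = x.max()
    if m == 0:
        return 0.0
    return float(np.sum(1.0 - x / m) / (x.size - 1))


# ---------------------------------------------------------------------------
# exon classification and conservation


@dataclass
class ExonRecord:
    interval: GenomicInterval
    gene_id: str
    exon_class: str  # circ_inside | parental_outside | non_parental | utr


def classify_exons(
    genes: list[GeneModel], circs: list[CircAnnotation]
) -> list[ExonRecord]:
    """Assign each collapsed exon to a class by circRNA membership.

    UTR-flagged exons take the ``utr`` class and are excluded from
    conservation comparisons downstream.  Coordinates are de-duplicated by
    per-gene collapsing before classification.
    """
    circ_exons: dict[str, list[GenomicInterval]] = {}
    for c in circs:
        circ_exons.setdefault(c.gene_id, []).extend(c.exons)
    records = []
    for gene in genes:
        parental = gene.gene_id in circ_exons
        cx = merge_intervals(circ_exons[gene.gene_id]) if parental else []
        for exon in gene.collapsed_exons():
            if any(
                exon.start < u_end and u_start < exon.end
                for u_start, u_end in gene.utr_exons
            ):
                cls = "utr"
            elif not parental:
                cls = "non_parental"
            elif any(exon.overlap(e) > 0 for e in cx):
                cls = "circ_inside"
            else:
                cls = "parental_outside"
            records.append(ExonRecord(exon, gene.gene_id, cls))
    return records


def phastcons_median(
    exons: list[ExonRecord], track: ConservationTrack
) -> pd.DataFrame:
    """Per-gene median of per-exon mean conservation scores, by class.

    UTR exons are excluded; exons without track coverage are skipped, not
    zero-filled.  Returns a tidy frame (gene_id, exon_class, median_score).
    """
    per_gene: dict[tuple[str, str], list[float]] = {}
    for rec in exons:
        if rec.exon_class == "utr":
            continue
        score = track.mean_score(rec.interval)
        if score is None:
            continue
        per_gene.setdefault((rec.gene_id, rec.exon_class), []).append(score)
    rows = [
        {"gene_id": g, "exon_class": c, "median_score": float(np.median(v))}
        for (g, c), v in sorted(per_gene.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "exon_class", "median_score"])


def exon_tissue_frequency(
    bins: list[tuple[GenomicInterval, str]],
    counts: dict[str, dict[int, int]],
    depths: dict[str, int],
    min_bin_length: int = 10,
    min_fpkm: float = 1.0,
) -> pd.DataFrame:
    """Tissues-expressed count per exon bin.

    ``bins`` pairs flattened, non-overlapping exon bins with their exon
    class; ``counts[tissue][bin_index]`` are read counts and ``depths``
    the library sizes.  Bins shorter than 10 nt are excluded; a bin is
    expressed in a tissue when FPKM = counts*1e9/(length*depth) >= 1.
    """
    rows = []
    for i, (iv, cls) in enumerate(bins):
        if len(iv) < min_bin_length:
            continue
        n_tissues = 0
        for tissue, depth in depths.items():
            c = counts.get(tissue, {}).get(i, 0)
            fpkm = c * 1e9 / (len(iv) * depth)
            if fpkm >= min_fpkm:
                n_tissues += 1
        rows.append(
            {"bin_index": i, "exon_class": cls, "length": len(iv),
             "tissues_expressed": n_tissues}
        )
    return pd.DataFrame(
        rows, columns=["bin_index", "exon_class", "length", "tissues_expressed"]
    )


# ---------------------------------------------------------------------------
# GC amplitude


@dataclass
class SpliceSiteAmplitude:
    gene_id: str
    position_class: str  # flanking | inside | outside
    amplitude: float  # log2(exonic GC / intronic GC)


def gc_amplitude_sites(
    gene: GeneModel,
    genome: str,
    circ_spans: list[GenomicInterval] | None = None,
    intron_window: int = 250,
    exon_window: int = 50,
    min_window: int = 10,
) -> list[SpliceSiteAmplitude]:
    """GC amplitudes of all splice sites of a gene.

    A site's amplitude is log2 of exonic-window GC over intronic-window GC,
    windows truncated at feature ends (skipped below ``min_window`` bases
    or when either window is GC-free).  Sites are classified relative to
    the gene's circRNA spans: flanking (at a span boundary), inside, or
    outside.
    """
    spans = circ_spans or []
    exons = gene.collapsed_exons()
    sites = []
    for i in range(len(exons) - 1):
        intron = (exons[i].end, exons[i + 1].start)
        for which, exon in (("donor", exons[i]), ("acceptor", exons[i + 1])):
            if which == "donor":
                e_seq = genome[max(exon.end - exon_window, exon.start) : exon.end]
                i_seq = genome[intron[0] : min(intron[0] + intron_window, intron[1])]
                boundary = exon.end
            else:
                e_seq = genome[exon.start : min(exon.start + exon_window, exon.end)]
                i_seq = genome[max(intron[1] - intron_window, intron[0]) : intron[1]]
                boundary = exon.start
            if len(e_seq) < min_window or len(i_seq) < min_window:
                continue
            gc_e, gc_i = gc_content(e_seq), gc_content(i_seq)
            if gc_e == 0 or gc_i == 0:
                continue  # degenerate window: skipped, not infinite
            if any(s.start == boundary or s.end == boundary for s in spans):
                cls = "flanking"
            elif any(s.start < boundary < s.end for s in spans):
                cls = "inside"
            else:
                cls = "outside"
            sites.append(
                SpliceSiteAmplitude(gene.gene_id, cls, float(np.log2(gc_e / gc_i)))
            )
    return sites


def amplitude_class_medians(sites: list[SpliceSiteAmplitude]) -> pd.DataFrame:
    per = {}
    for s in sites:
        per.setdefault((s.gene_id, s.position_class), []).append(s.amplitude)
    rows = [
        {"gene_id": g, "position_class": c, "median_amplitude": float(np.median(v))}
        for (g, c), v in sorted(per.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "position_class",
                                       "median_amplitude"])


def paired_rank_test(a, b, alternative: str = "greater") -> float:
    """One-tailed paired Wilcoxon signed-rank p-value for a vs. b."""
    return float(stats.wilcoxon(a, b, alternative=alternative).pvalue)


# ---------------------------------------------------------------------------
# generalized linear models


class DegenerateDesignError(ValueError):
    pass


@dataclass
class GlmFit:
    selected: list[str]
    log_odds: dict[str, float]
    p_values: dict[str, float]
    validation_log_odds: dict[str, float]
    accuracy: float
    sensitivity: float
    specificity: float
    vif: dict[str, float]
    separation_flag: bool = False
    notes: list[str] = field(default_factory=list)


def _standardize(x: pd.DataFrame) -> pd.DataFrame:
    sd = x.std(ddof=0)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise DegenerateDesignError(f"constant predictors: {bad}")
    return (x - x.mean()) / sd


def _vif(x: pd.DataFrame) -> dict[str, float]:
    out = {}
    xv = x.values
    for i, col in enumerate(x.columns):
        others = np.delete(xv, i, axis=1)
        if others.shape[1] == 0:
            out[col] = 1.0
            continue
        design = np.column_stack([np.ones(len(xv)), others])
        beta, *_ = np.linalg.lstsq(design, xv[:, i], rcond=None)
        resid = xv[:, i] - design @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((xv[:, i] - xv[:, i].mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        out[col] = 1.0 / (1.0 - r2) if r2 < 1 else float("inf")
    return out


def _make_splits(
    n: int, rng: np.random.Generator, reps: int, holdout: float = 0.25
) -> list[tuple[np.ndarray, np.ndarray]]:
    cut = int(round(n * (1 - holdout)))
    splits = []
    for _ in range(reps):
        perm = rng.permutation(n)
        splits.append((perm[:cut], perm[cut:]))
    return splits


def _irls_logit(design: np.ndarray, y: np.ndarray, max_iter: int = 30,
                tol: float = 1e-9) -> np.ndarray:
    """Plain Newton/IRLS maximum-likelihood logistic fit (design includes
    the intercept column).  Diverging coefficients (separation) are capped."""
    beta = np.zeros(design.shape[1])
    for _ in range(max_iter):
        eta = design @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1 - p), 1e-10)
        z = eta + (y - p) / w
        xtw = design.T * w
        try:
            new = np.linalg.solve(xtw @ design, xtw @ z)
        except np.linalg.LinAlgError:
            break
        done = np.max(np.abs(new - beta)) < tol
        beta = new
        if done or np.max(np.abs(beta)) > 30:
            break
    return beta


def _cv_loss(
    x: np.ndarray, y: np.ndarray, cols: tuple[int, ...],
    splits: list[tuple[np.ndarray, np.ndarray]],
) -> float:
    """Mean held-out log-loss over shared train/test splits.

    All candidate subsets are scored on the same splits so that model
    comparisons are paired and split noise cancels."""
    losses = []
    for tr, te in splits:
        if len(set(y[tr])) < 2:
            continue
        if cols:
            design = np.column_stack([np.ones(len(tr)), x[np.ix_(tr, cols)]])
            beta = _irls_logit(design, y[tr].astype(float))
            eta = np.column_stack(
                [np.ones(len(te)), x[np.ix_(te, cols)]]
            ) @ beta
            p = 1.0 / (1.0 + np.exp(-eta))
        else:
            p = np.full(len(te), y[tr].mean())
        p = np.clip(p, 1e-12, 1 - 1e-12)
        losses.append(
            -np.mean(y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p))
        )
    return float(np.mean(losses)) if losses else float("inf")


def fit_glm(
    table: pd.DataFrame,
    response: str,
    split: float = 0.8,
    cv_reps: int = 100,
    seed: int = 0,
    max_exhaustive: int = 10,
    vif_threshold: float = 5.0,
) -> GlmFit:
    """Best-subset binomial GLM with cross-validated selection.

    Predictors (every column except ``response``) are standardized to mean
    0 and unit variance, so coefficients are standardized log-odds.  The
    best subset minimizes repeated-random-split cross-validated log-loss on
    the ``split`` training fraction (exhaustive up to ``max_exhaustive``
    predictors, greedy forward beyond).  Headline coefficients and
    p-values come from a maximum-likelihood fit of the selected model on
    the full standardized data; accuracy, sensitivity and specificity are
    computed on the held-out validation fraction from a training-only fit
    at a probability cut-off of 0.5, and a validation-only refit's
    coefficients are reported alongside.
    """
    rng = np.random.default_rng(seed)
    y_all = table[response].to_numpy(dtype=float)
    if len(set(y_all)) < 2:
        raise DegenerateDesignError("response takes a single value")
    predictors = [c for c in table.columns if c != response]
    x_std = _standardize(table[predictors])
    vif = _vif(x_std)
    notes = [
        f"VIF>{vif_threshold}: {c}" for c, v in vif.items() if v > vif_threshold
    ]
    n = len(table)
    perm = rng.permutation(n)
    cut = int(round(n * split))
    train_idx, valid_idx = perm[:cut], perm[cut:]
    x = x_std.to_numpy()
    y = y_all.astype(int)

    p = len(predictors)
    xt, yt = x[train_idx], y[train_idx]
    splits = _make_splits(len(yt), rng, cv_reps)
    if p <= max_exhaustive:
        subsets = [()] + [
            cols for k in range(1, p + 1) for cols in combinations(range(p), k)
        ]
        losses = {cols: _cv_loss(xt, yt, cols, splits) for cols in subsets}
        best_cols = min(losses, key=losses.get)
    else:  # greedy forward selection
        remaining = list(range(p))
        best_cols: tuple[int, ...] = ()
        best_loss = _cv_loss(xt, yt, best_cols, splits)
        improved = True
        while improved and remaining:
            improved = False
            for c in list(remaining):
                cand = tuple(sorted(best_cols + (c,)))
                loss = _cv_loss(xt, yt, cand, splits)
                if loss < best_loss:
                    best_loss, best_cols = loss, cand
                    remaining.remove(c)
                    improved = True
    selected = [predictors[i] for i in best_cols]

    def _ml_fit(rows: np.ndarray) -> tuple[dict, dict, bool]:
        design = sm.add_constant(
            pd.DataFrame(x[np.ix_(rows, best_cols)], columns=selected),
            has_constant="add",
        )
        flag = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y[rows], design).fit(disp=0)
            except Exception:
                flag = True
                clf = LogisticRegression(C=1e6, max_iter=500)
                if selected:
                    clf.fit(x[np.ix_(rows, best_cols)], y[rows])
                    coefs = dict(zip(selected, clf.coef_[0]))
                else:
                    coefs = {}
                return coefs, {k: float("nan") for k in coefs}, flag
        if not flag and np.any(np.abs(res.params) > 20):
            flag = True  # quasi-separation
        coefs = {k: float(res.params[k]) for k in selected}
        pvals = {k: float(res.pvalues[k]) for k in selected}
        return coefs, pvals, flag

    log_odds, p_values, sep_full = _ml_fit(np.arange(n))
    validation_log_odds, _, sep_val = _ml_fit(valid_idx) if len(valid_idx) else ({}, {}, False)

    # held-out metrics from a training-only fit
    if selected:
        clf = LogisticRegression(C=np.inf, max_iter=500)
        clf.fit(x[np.ix_(train_idx, best_cols)], y[train_idx])
        prob = clf.predict_proba(x[np.ix_(valid_idx, best_cols)])[:, 1]
    else:
        prob = np.full(len(valid_idx), y[train_idx].mean())
    pred = (prob >= 0.5).astype(int)
    yv = y[valid_idx]
    tp = int(((pred == 1) & (yv == 1)).sum())
    tn = int(((pred == 0) & (yv == 0)).sum())
    fp = int(((pred == 1) & (yv == 0)).sum())
    fn = int(((pred == 0) & (yv == 1)).sum())
    accuracy = (tp + tn) / len(yv) if len(yv) else float("nan")
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")

    return GlmFit(
        selected=selected,
        log_odds=log_odds,
        p_values=p_values,
        validation_log_odds=validation_log_odds,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        vif=vif,
        separation_flag=sep_full or sep_val,
        notes=notes,
    )


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def glm_report(fit: GlmFit) -> dict:
    """JSON-ready model report: per-predictor standardized log-odds with
    significance stars, plus validation metrics."""
    return {
        "predictors": [
            {
                "predictor": k,
                "log_odds": fit.log_odds[k],
                "p_value": fit.p_values.get(k, float("nan")),
                "significance": significance_stars(
                    fit.p_values.get(k, float("nan"))
                ),
            }
            for k in fit.selected
        ],
        "accuracy": fit.accuracy,
        "sensitivity": fit.sensitivity,
        "specificity": fit.specificity,
        "separation_flag": fit.separation_flag,
        "notes": fit.notes,
    }


def fit_sharing_glm(
    table: pd.DataFrame,
    response: str = "is_hotspot",
    clade_col: str = "clade",
    reference: str = "species-specific",
) -> dict:
    """Logistic model of hotspot status on the clade-sharing category.

    The reference category is species-specific; log-odds are reported per
    clade level.  Raises on degenerate (single-category) designs.
    """
    clades = table[clade_col].astype(str)
    levels = [c for c in pd.unique(clades) if c != reference]
    if not levels or reference not in set(clades):
        raise DegenerateDesignError("clade design has a single category")
    dummies = pd.get_dummies(clades)[levels].astype(float)
    design = sm.add_constant(dummies, has_constant="add")
    y = table[response].astype(int).to_numpy()
    if len(set(y)) < 2:
        raise DegenerateDesignError("response takes a single value")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, design).fit(disp=0)
    return {
        "log_odds": {k: float(res.params[k]) for k in levels},
        "p_values": {k: float(res.pvalues[k]) for k in levels},
        "reference": reference,
    }
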