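"""Reverse-complement self-alignment, TE dimers and pairing scores.

A gene's pre-mRNA can base-pair with itself where two intronic regions are
reverse complements (RVCs), typically because two copies of the same TE
family inserted in opposite orientations; such "dimers" bring backsplice
sites into proximity.  This module finds RVCs by seeded ungapped
self-alignment, samples GC/length-matched control introns, quantifies TE
enrichment, calls the strongest repeat dimer per RVC (>= 50% of each
repeat's length inside the paired segments), corrects dimer counts for
repeats participating in several RVCs, ranks dimer classes by corrected
frequency and shared-vs-specific enrichment, and scores family pairing
potential from consensus distances plus co-fold energies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from circevo.formats import GeneModel, GenomicInterval, RepeatCopy, revcomp

try:  # the dynamic program is O(n^3); numba keeps genomic-scale calls fast
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None


@dataclass
class RVC:
    """A pair of intragenic segments joined by an ungapped self-alignment."""

    gene_id: str
    segment_a: GenomicInterval
    segment_b: GenomicInterval
    alignment_length: int
    identity: float
    orientation: str  # sense | antisense


@dataclass
class DimerCall:
    gene_id: str
    rvc: RVC
    repeat_a: RepeatCopy
    repeat_b: RepeatCopy
    overlap_a: int
    overlap_b: int
    corrected_count: float = 1.0
    mean_age: float = float("nan")
    mfe: float | None = None

    @property
    def key(self) -> tuple[str, str]:
        """Unordered family pair (A+B is the same dimer class as B+A)."""
        return tuple(sorted((self.repeat_a.family, self.repeat_b.family)))


# ---------------------------------------------------------------------------
# RVC detection


def _extend_ungapped(
    a: str, b: str, i: int, j: int, w: int, xdrop: int = 12
) -> tuple[int, int, int, int]:
    """Extend an exact seed a[i:i+w]==b[j:j+w] in both directions.

    Match +1 / mismatch -2 scoring with an X-drop cut-off; returns
    (start_offset_left, end_offset_right, length, matches)."""
    best_r, m_r = 0, 0
    score, best_score, m = 0, 0, 0
    t = 0
    while i + w + t < len(a) and j + w + t < len(b):
        m += 1 if a[i + w + t] == b[j + w + t] else 0
        t += 1
        score = m - 2 * (t - m)
        if score > best_score:
            best_score, best_r, m_r = score, t, m
        if score < best_score - xdrop:
            break
    best_l, m_l = 0, 0
    score, best_score, m = 0, 0, 0
    t = 0
    while i - 1 - t >= 0 and j - 1 - t >= 0:
        m += 1 if a[i - 1 - t] == b[j - 1 - t] else 0
        t += 1
        score = m - 2 * (t - m)
        if score > best_score:
            best_score, best_l, m_l = score, t, m
        if score < best_score - xdrop:
            break
    length = w + best_l + best_r
    matches = w + m_l + m_r
    return best_l, best_r, length, matches


def _seeded_alignments(
    a: str, b: str, word_size: int, min_identity: float, min_length: int,
    exclude_self_diagonal: bool,
):
    """All ungapped local alignments between a and b found from exact seeds."""
    index: dict[str, list[int]] = {}
    for i in range(0, len(a) - word_size + 1):
        index.setdefault(a[i : i + word_size], []).append(i)
    covered: dict[int, list[tuple[int, int]]] = {}
    out = []
    for j in range(0, len(b) - word_size + 1):
        for i in index.get(b[j : j + word_size], ()):
            d = i - j
            if exclude_self_diagonal and d == 0:
                continue
            if any(s <= j < e for s, e in covered.get(d, ())):
                continue
            left, right, length, matches = _extend_ungapped(a, b, i, j, word_size)
            covered.setdefault(d, []).append((j - left, j + word_size + right))
            if length >= min_length and matches / length >= min_identity:
                out.append((i - left, j - left, length, matches / length))
    return out


def find_rvc(
    gene: GeneModel,
    genome: str,
    word_size: int = 12,
    min_identity: float = 0.8,
    min_length: int = 50,
) -> tuple[list[RVC], float]:
    """Seeded ungapped self-alignment of a gene (first to last exon) in
    sense and antisense orientation.

    Returns the RVC list and the per-gene self-complementarity fraction
    (merged alignment length over gene length).  The trivial self-diagonal
    is excluded; symmetric duplicates are canonicalized away.
    """
    start, end = gene.start, gene.end
    seq = genome[start:end]
    n = len(seq)
    rvcs: list[RVC] = []
    seen: set[tuple] = set()

    def _add(a0: int, a1: int, b0: int, b1: int, length: int, ident: float,
             orientation: str):
        if (a0, a1) > (b0, b1):
            a0, a1, b0, b1 = b0, b1, a0, a1
        key = (a0, a1, b0, b1, orientation)
        if key in seen or (a0, a1) == (b0, b1):
            return
        seen.add(key)
        rvcs.append(
            RVC(
                gene.gene_id,
                GenomicInterval(gene.chrom, start + a0, start + a1, "+"),
                GenomicInterval(gene.chrom, start + b0, start + b1, "-"),
                length,
                ident,
                orientation,
            )
        )

    # antisense: gene vs. its reverse complement
    rc = revcomp(seq)
    for i, j, length, ident in _seeded_alignments(
        seq, rc, word_size, min_identity, min_length, exclude_self_diagonal=False
    ):
        b1 = n - j  # rc[j:j+len] is revcomp(seq[n-j-len : n-j])
        b0 = n - j - length
        _add(i, i + length, b0, b1, length, ident, "antisense")

    # sense duplications: gene vs. itself off the main diagonal
    for i, j, length, ident in _seeded_alignments(
        seq, seq, word_size, min_identity, min_length, exclude_self_diagonal=True
    ):
        _add(i, i + length, j, j + length, length, ident, "sense")

    from circevo.formats import merge_intervals

    segs = [r.segment_a for r in rvcs] + [r.segment_b for r in rvcs]
    merged_len = sum(len(iv) for iv in merge_intervals(segs)) if segs else 0
    return rvcs, merged_len / n if n else 0.0


def filter_intronic_rvcs(rvcs: list[RVC], gene: GeneModel) -> list[RVC]:
    """Keep RVCs whose two segments are purely intronic (no exon overlap)."""
    exons = gene.collapsed_exons()
    out = []
    for r in rvcs:
        if any(r.segment_a.overlap(e) > 0 or r.segment_b.overlap(e) > 0
               for e in exons):
            continue
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# control introns


@dataclass
class IntronRecord:
    interval: GenomicInterval
    gc: float

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass
class ControlIntronSet:
    flanking: list[IntronRecord]
    control: list[IntronRecord]
    excluded_flanking: list[IntronRecord]
    p_gc: float
    p_length: float
    borrowed_bins: int = 0


def match_control_introns(
    flanking: list[IntronRecord],
    candidates: list[IntronRecord],
    seed: int,
    gc_bin: float = 0.01,
    length_bin: int = 1000,
) -> ControlIntronSet:
    """Sample a control intron set matched to the flanking introns in a
    GC x length bin grid spanning the flanking 5-95% quantiles.

    Flanking introns outside the grid are excluded (and reported);
    under-filled bins borrow from the nearest non-empty candidate bin by
    Euclidean bin distance.  Distribution equivalence is summarized by
    two-sample KS p-values on GC and length.
    """
    rng = np.random.default_rng(seed)
    gcs = np.array([f.gc for f in flanking])
    lens = np.array([f.length for f in flanking])
    gc_lo, gc_hi = np.quantile(gcs, [0.05, 0.95])
    len_lo, len_hi = np.quantile(lens, [0.05, 0.95])

    def _bin(rec: IntronRecord) -> tuple[int, int] | None:
        if not (gc_lo <= rec.gc <= gc_hi and len_lo <= rec.length <= len_hi):
            return None
        return (
            int((rec.gc - gc_lo) / gc_bin),
            int((rec.length - len_lo) / length_bin),
        )

    in_grid, excluded = [], []
    need: dict[tuple[int, int], int] = {}
    for f in flanking:
        b = _bin(f)
        if b is None:
            excluded.append(f)
        else:
            in_grid.append(f)
            need[b] = need.get(b, 0) + 1
    pool: dict[tuple[int, int], list[IntronRecord]] = {}
    for c in candidates:
        b = _bin(c)
        if b is not None:
            pool.setdefault(b, []).append(c)

    control: list[IntronRecord] = []
    borrowed = 0
    for b, k in sorted(need.items()):
        available = list(pool.get(b, []))
        take = min(k, len(available))
        if take:
            picks = rng.choice(len(available), size=take, replace=False)
            control.extend(available[i] for i in picks)
        short = k - take
        if short > 0:
            borrowed += 1
            warnings.warn(f"bin {b} under-filled; borrowing {short} from neighbours")
            others = sorted(
                (bb for bb in pool if bb != b and pool[bb]),
                key=lambda bb: (bb[0] - b[0]) ** 2 + (bb[1] - b[1]) ** 2,
            )
            for bb in others:
                avail = pool[bb]
                take2 = min(short, len(avail))
                picks = rng.choice(len(avail), size=take2, replace=False)
                control.extend(avail[i] for i in picks)
                short -= take2
                if short == 0:
                    break
    if in_grid and control:
        p_gc = float(
            stats.ks_2samp([f.gc for f in in_grid], [c.gc for c in control]).pvalue
        )
        p_len = float(
            stats.ks_2samp(
                [f.length for f in in_grid], [c.length for c in control]
            ).pvalue
        )
    else:
        p_gc = p_len = float("nan")
    return ControlIntronSet(in_grid, control, excluded, p_gc, p_len, borrowed)


def te_enrichment(
    flanking: list[IntronRecord],
    control: ControlIntronSet,
    repeats: list[RepeatCopy],
) -> pd.DataFrame:
    """Per-family TE counts in flanking vs. matched control introns.

    Introns are paired positionally (i-th flanking with i-th control);
    enrichment is the mean paired count difference, tested with the
    Wilcoxon signed-rank test.  Families absent from both groups are
    excluded."""
    n = min(len(control.flanking), len(control.control))
    flank = control.flanking[:n]
    ctrl = control.control[:n]
    families = sorted({r.family for r in repeats})

    def _counts(introns: list[IntronRecord], family: str) -> np.ndarray:
        return np.array(
            [
                sum(
                    1
                    for r in repeats
                    if r.family == family and r.interval.overlap(iv.interval) > 0
                )
                for iv in introns
            ]
        )

    rows = []
    for fam in families:
        a = _counts(flank, fam)
        b = _counts(ctrl, fam)
        if a.sum() == 0 and b.sum() == 0:
            continue
        diff = a - b
        if np.all(diff == 0):
            pval = 1.0
        else:
            pval = float(stats.wilcoxon(a, b, zero_method="wilcox").pvalue)
        rows.append(
            {"family": fam, "enrichment": float(diff.mean()), "p_value": pval}
        )
    return pd.DataFrame(rows, columns=["family", "enrichment", "p_value"])


# ---------------------------------------------------------------------------
# dimers


def call_dimers(
    rvcs: list[RVC],
    repeats: list[RepeatCopy],
    age_of_family: dict[str, int] | None = None,
    min_frac: float = 0.5,
) -> list[DimerCall]:
    """Per RVC, call the strongest repeat dimer.

    A repeat is a candidate for a segment when at least ``min_frac`` of its
    own length overlaps the segment; among candidate pairs the one with
    the largest total overlapping bases wins (ties: lower mean milliDiv,
    then leftmost coordinates)."""
    calls = []
    for rvc in rvcs:
        cands = {}
        for seg_name, seg in (("a", rvc.segment_a), ("b", rvc.segment_b)):
            cands[seg_name] = [
                (r, r.interval.overlap(seg))
                for r in repeats
                if r.interval.overlap(seg) >= min_frac * len(r.interval)
            ]
        best = None
        for ra, ova in cands["a"]:
            for rb, ovb in cands["b"]:
                if ra is rb:
                    continue
                key = (
                    -(ova + ovb),
                    (ra.milli_div + rb.milli_div) / 2,
                    ra.interval.start,
                    rb.interval.start,
                )
                if best is None or key < best[0]:
                    best = (key, ra, rb, ova, ovb)
        if best is None:
            continue
        _, ra, rb, ova, ovb = best
        mean_age = float("nan")
        if age_of_family:
            mean_age = (
                age_of_family.get(ra.family, np.nan)
                + age_of_family.get(rb.family, np.nan)
            ) / 2
        calls.append(DimerCall(rvc.gene_id, rvc, ra, rb, ova, ovb,
                               mean_age=mean_age))
    return calls


def correct_cocounts(dimers: list[DimerCall]) -> list[DimerCall]:
    """Down-weight dimers whose repeats participate in several calls.

    Each dimer's corrected count is 1 over the mean participation count of
    its two repeat copies, so the corrected total never exceeds the raw
    dimer count (equality iff every repeat appears in exactly one dimer).
    """
    participation: dict[tuple, int] = {}

    def _rid(r: RepeatCopy) -> tuple:
        return (r.interval.chrom, r.interval.start, r.interval.end, r.family)

    for d in dimers:
        participation[_rid(d.repeat_a)] = participation.get(_rid(d.repeat_a), 0) + 1
        participation[_rid(d.repeat_b)] = participation.get(_rid(d.repeat_b), 0) + 1
    for d in dimers:
        factor = (participation[_rid(d.repeat_a)] + participation[_rid(d.repeat_b)]) / 2
        d.corrected_count = 1.0 / factor
    return dimers


def dimer_table(dimers: list[DimerCall]) -> pd.DataFrame:
    """Tidy per-call dimer table (one row per called dimer)."""
    rows = [
        {
            "gene_id": d.gene_id,
            "family_a": d.repeat_a.family,
            "family_b": d.repeat_b.family,
            "rvc_a": f"{d.rvc.segment_a.chrom}:{d.rvc.segment_a.start}-{d.rvc.segment_a.end}",
            "rvc_b": f"{d.rvc.segment_b.chrom}:{d.rvc.segment_b.start}-{d.rvc.segment_b.end}",
            "overlap_a": d.overlap_a,
            "overlap_b": d.overlap_b,
            "corrected_count": d.corrected_count,
            "mean_age": d.mean_age,
            "millidiv_a": d.repeat_a.milli_div,
            "millidiv_b": d.repeat_b.milli_div,
            "mfe": d.mfe,
        }
        for d in dimers
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "family_a", "family_b", "rvc_a", "rvc_b",
                 "overlap_a", "overlap_b", "corrected_count", "mean_age",
                 "millidiv_a", "millidiv_b", "mfe"],
    )


def write_dimer_track(dimers: list[DimerCall], path) -> None:
    """BED-like arc track pairing the two repeat copies of each dimer, for
    genome-browser-style visualization."""
    with open(path, "w") as fh:
        for d in dimers:
            a, b = d.repeat_a.interval, d.repeat_b.interval
            name = f"{d.gene_id}|{d.repeat_a.family}+{d.repeat_b.family}"
            fh.write(
                f"{a.chrom}\t{a.start}\t{b.end}\t{name}\t"
                f"{d.corrected_count:.4g}\t{a.start}-{a.end},{b.start}-{b.end}\n"
            )


@dataclass
class DimerRanking:
    table: pd.DataFrame  # per dimer class
    top5: list[tuple[str, str]]
    top5_share: float
    top5_mean_age: float
    background_mean_age: float
    signed_rank_p: float | None


def rank_dimers(
    dimers_shared: list[DimerCall],
    dimers_specific: list[DimerCall],
    n_genes_shared: int,
    n_genes_specific: int,
    top_n: int = 100,
) -> DimerRanking:
    """Rank dimer classes (unordered family pairs) by corrected frequency.

    The per-class log2 enrichment compares mean per-gene corrected
    frequency in shared vs. species-specific circRNA loci; the top-5 set
    is the most frequent positively enriched classes.  The shared and
    specific frequency distributions of the ``top_n`` most and least
    frequent classes are compared with a Wilcoxon signed-rank test.
    """
    keys = sorted({d.key for d in dimers_shared + dimers_specific})
    rows = []
    for key in keys:
        f_sh = sum(d.corrected_count for d in dimers_shared if d.key == key)
        f_sp = sum(d.corrected_count for d in dimers_specific if d.key == key)
        mean_sh = f_sh / n_genes_shared if n_genes_shared else 0.0
        mean_sp = f_sp / n_genes_specific if n_genes_specific else 0.0
        if mean_sh > 0 and mean_sp > 0:
            enr = float(np.log2(mean_sh / mean_sp))
        elif mean_sh > 0:
            enr = float("inf")
        elif mean_sp > 0:
            enr = float("-inf")
        else:
            enr = float("nan")
        ages = [
            d.mean_age
            for d in dimers_shared + dimers_specific
            if d.key == key and np.isfinite(d.mean_age)
        ]
        rows.append(
            {
                "family_a": key[0],
                "family_b": key[1],
                "frequency": f_sh + f_sp,
                "mean_freq_shared": mean_sh,
                "mean_freq_specific": mean_sp,
                "log2_enrichment": enr,
                "mean_age": float(np.mean(ages)) if ages else float("nan"),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["family_a", "family_b", "frequency", "mean_freq_shared",
                 "mean_freq_specific", "log2_enrichment", "mean_age"],
    ).sort_values("frequency", ascending=False, ignore_index=True)
    total = table["frequency"].sum()
    enriched = table[table["log2_enrichment"] > 0]
    top5_df = enriched.head(5)
    top5 = [tuple(r) for r in top5_df[["family_a", "family_b"]].itertuples(index=False)]
    top5_share = float(top5_df["frequency"].sum() / total) if total else 0.0
    top5_mean_age = (
        float(top5_df["mean_age"].mean()) if len(top5_df) else float("nan")
    )
    background_mean_age = (
        float(table["mean_age"].mean()) if len(table) else float("nan")
    )
    sel = pd.concat([table.head(top_n), table.tail(top_n)]).drop_duplicates(
        subset=["family_a", "family_b"]
    )
    p = None
    if len(sel) >= 2:
        diff = sel["mean_freq_shared"] - sel["mean_freq_specific"]
        if np.any(diff != 0):
            p = float(
                stats.wilcoxon(
                    sel["mean_freq_shared"], sel["mean_freq_specific"],
                    zero_method="wilcox",
                ).pvalue
            )
        else:
            p = 1.0
    return DimerRanking(table, top5, top5_share, top5_mean_age,
                        background_mean_age, p)


# ---------------------------------------------------------------------------
# consensus distances and co-fold energy


def consensus_distance(consensus: dict[str, str]) -> pd.DataFrame:
    """Pairwise global-alignment distances (1 - identity) between TE family
    consensus sequences; symmetric with a zero diagonal."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -0.5
    names = sorted(consensus)
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            matches = 0.0
            aln = aligner.align(consensus[a], consensus[b])[0]
            sa, sb = aln[0], aln[1]
            matches = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
            ident = matches / max(len(consensus[a]), len(consensus[b]))
            mat.loc[a, b] = mat.loc[b, a] = 1.0 - ident
    return mat


_PAIR_WEIGHTS = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "T"): 2, ("T", "A"): 2, ("A", "U"): 2, ("U", "A"): 2,
    ("G", "T"): 1, ("T", "G"): 1, ("G", "U"): 1, ("U", "G"): 1,
}


def _pair_weight_table() -> np.ndarray:
    w = np.zeros((128, 128), dtype=np.int64)
    for (x, y), v in _PAIR_WEIGHTS.items():
        w[ord(x), ord(y)] = v
    return w


_WTAB = _pair_weight_table()


def _nussinov_py(codes: np.ndarray, min_loop: int) -> int:
    n = len(codes)
    dp = np.zeros((n, n), dtype=np.int64)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1, j]
            w = _WTAB[codes[i], codes[j]]
            if w > 0:
                v = w + (dp[i + 1, j - 1] if j - 1 >= i + 1 else 0)
                if v > best:
                    best = v
            for k in range(i, j):
                v = dp[i, k] + dp[k + 1, j]
                if v > best:
                    best = v
            dp[i, j] = best
    return int(dp[0, n - 1])


if njit is not None:
    _nussinov_jit = njit(cache=False)(_nussinov_py)
else:  # pragma: no cover
    _nussinov_jit = _nussinov_py


def cofold_mfe(seq_a: str, seq_b: str, min_loop: int = 3) -> float:
    """Co-fold energy proxy of two sequences.

    A Nussinov-style dynamic program maximizes weighted base pairs (GC 3,
    AU 2, GU 1; minimum loop 3) on the concatenation of the two sequences
    joined by a linker that cannot pair; the energy is minus the optimal
    weight — a monotone proxy for duplex stability, not a thermodynamic
    free energy.  A pluggable external folding backend with the same call
    contract can replace it for real data.
    """
    s = (seq_a + "NNN" + seq_b).upper().replace("U", "T")
    codes = np.frombuffer(s.encode(), dtype=np.uint8).astype(np.int64)
    if len(codes) < 2:
        return 0.0
    return -float(_nussinov_jit(codes, min_loop))


def pairing_score(
    distance: pd.DataFrame, mfe: pd.DataFrame
) -> dict:
    """Min-max standardize the distance and co-fold matrices, sum them into
    pairing scores in [0, 2], and classify families by PCA (centered,
    unscaled) of their score rows."""
    def _std(m: pd.DataFrame, name: str) -> pd.DataFrame:
        v = m.values.astype(float)
        lo, hi = v.min(), v.max()
        if hi == lo:
            raise ValueError(f"{name} matrix is constant; standardization undefined")
        return (m - lo) / (hi - lo)

    if list(distance.index) != list(mfe.index):
        mfe = mfe.loc[distance.index, distance.columns]
    score = _std(distance, "distance") + _std(mfe, "mfe")
    x = score.values - score.values.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2 / max(len(x) - 1, 1)
    var_explained = var / var.sum() if var.sum() > 0 else var
    pcs = u * s
    return {
        "score": score,
        "pc1": pd.Series(pcs[:, 0], index=score.index),
        "pc2": pd.Series(pcs[:, 1] if pcs.shape[1] > 1 else np.zeros(len(x)),
                         index=score.index),
        "variance_explained": var_explained[:2].tolist(),
    }


# ---------------------------------------------------------------------------
# degradation


def degradation_analysis(
    dimers: list[DimerCall],
    gene_group: dict[str, str],  # gene_id -> shared | species-specific
    top5: list[tuple[str, str]],
    genome: str | None = None,
) -> dict:
    """Degradation (milliDiv) and binding-energy contrasts between shared
    and species-specific circRNA loci.

    milliDiv values of all repeat copies in top-5 dimers are compared by
    rank-sum test; per gene the least-degraded dimer (minimal mean
    milliDiv) is selected and, when a genome is supplied, its two genomic
    repeat sequences are co-folded; energies are compared by t-test when
    both groups have at least three observations (otherwise skipped with a
    notice)."""
    top5_set = set(top5)
    md = {"shared": [], "species-specific": []}
    for d in dimers:
        grp = gene_group.get(d.gene_id)
        if grp in md and d.key in top5_set:
            md[grp] += [d.repeat_a.milli_div, d.repeat_b.milli_div]
    p_millidiv = None
    if md["shared"] and md["species-specific"]:
        p_millidiv = float(
            stats.mannwhitneyu(md["shared"], md["species-specific"]).pvalue
        )

    least: dict[str, DimerCall] = {}
    for d in dimers:
        mean_md = (d.repeat_a.milli_div + d.repeat_b.milli_div) / 2
        cur = least.get(d.gene_id)
        if cur is None or mean_md < (cur.repeat_a.milli_div + cur.repeat_b.milli_div) / 2:
            least[d.gene_id] = d

    energies = {"shared": [], "species-specific": []}
    if genome is not None:
        for gid, d in least.items():
            grp = gene_group.get(gid)
            if grp not in energies:
                continue
            sa = genome[d.repeat_a.interval.start : d.repeat_a.interval.end]
            sb = genome[d.repeat_b.interval.start : d.repeat_b.interval.end]
            d.mfe = cofold_mfe(sa, sb)
            energies[grp].append(d.mfe)
    p_mfe = None
    notice = None
    if genome is not None:
        if len(energies["shared"]) >= 3 and len(energies["species-specific"]) >= 3:
            p_mfe = float(
                stats.ttest_ind(energies["shared"], energies["species-specific"]).pvalue
            )
        else:
            notice = "co-fold energy test skipped: fewer than 3 genes per group"
    return {
        "millidiv": md,
        "p_millidiv": p_millidiv,
        "least_degraded": least,
        "energies": energies,
        "p_mfe": p_mfe,
        "notice": notice,
    }
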