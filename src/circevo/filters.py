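"""High-confidence circRNA filter cascade on the junction count matrix.

Four ordered steps: (1) paired/singleton mapping-mode consistency between
the untreated and RNase R-treated sample of each biological replicate,
(2) presence in at least one untreated replicate, (3) median-of-ratios
size-factor normalization and a minimum log2 treated/untreated enrichment
of 1.5, (4) a minimum expression of 0.05 counts per million in at least
one tissue.  A blacklist of manually curated repetitive regions can be
applied afterwards.  Every step appends to a telescoping report.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from circevo.formats import GenomicInterval

DEFAULT_MIN_LOG2_ENRICHMENT = 1.5
DEFAULT_MIN_CPM = 0.05


class FilterError(ValueError):
    pass


@dataclass
class FilterReport:
    steps: list[dict] = field(default_factory=list)

    def add(self, name: str, n_in: int, removed: int) -> None:
        self.steps.append(
            {
                "step": name,
                "in": n_in,
                "removed": removed,
                "fraction_removed": removed / n_in if n_in else 0.0,
            }
        )

    def telescopes(self) -> bool:
        for prev, cur in zip(self.steps, self.steps[1:]):
            if prev["in"] - prev["removed"] != cur["in"]:
                return False
        return True


@dataclass
class JunctionCountMatrix:
    """Backsplice-junction x sample counts with sample metadata.

    ``samples`` is indexed by sample id with columns species, tissue,
    replicate, condition ('untreated'/'treated') and mapped_reads;
    ``counts`` is junctions x samples; ``pe_se`` (optional) holds the
    mapping mode ('pe'/'se'/None) per junction and sample.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    pe_se: pd.DataFrame | None = None
    intervals: dict[str, GenomicInterval] = field(default_factory=dict)

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise FilterError("counts must be non-negative")
        for cond in ("untreated", "treated"):
            if cond not in set(self.samples["condition"]):
                raise FilterError(f"no {cond} samples present")

    def subset(self, junction_ids) -> "JunctionCountMatrix":
        ids = list(junction_ids)
        return JunctionCountMatrix(
            counts=self.counts.loc[ids],
            samples=self.samples,
            pe_se=self.pe_se.loc[ids] if self.pe_se is not None else None,
            intervals={j: iv for j, iv in self.intervals.items() if j in set(ids)},
        )

    @property
    def junction_ids(self) -> list[str]:
        return list(self.counts.index)


def junction_id(iv: GenomicInterval) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}:{iv.strand}"


def build_matrix(candidates, aligned) -> JunctionCountMatrix:
    """Assemble the junction count matrix from detection output.

    ``candidates`` are backsplice candidates with per-sample support sets;
    ``aligned`` maps library keys to aligned libraries (for mapped totals
    and pair modes).  The pe/se mode of a junction in a sample is the
    majority mode of its supporting pairs: 'pe' when the mate of the
    junction-spanning read also mapped.
    """
    sample_rows = {}
    mode_by_read: dict[str, str] = {}
    for key, al in aligned.items():
        sample_rows[key.sample_id] = {
            "species": key.species,
            "tissue": key.tissue,
            "replicate": key.replicate,
            "condition": key.condition,
            "mapped_reads": al.n_mapped_reads,
        }
        mode_by_read.update(al.pair_modes)
    samples = pd.DataFrame.from_dict(sample_rows, orient="index")
    counts = pd.DataFrame(
        0, index=[junction_id(c.interval) for c in candidates],
        columns=samples.index, dtype=int,
    )
    pe_se = pd.DataFrame(None, index=counts.index, columns=samples.index,
                         dtype=object)
    intervals = {}
    for cand in candidates:
        jid = junction_id(cand.interval)
        intervals[jid] = cand.interval
        for sample, reads in cand.support.items():
            if sample not in counts.columns:
                continue
            pairs = {key.rpartition("#")[0] for key in reads}
            counts.loc[jid, sample] = len(pairs)
            if pairs:
                # a junction pair is 'pe' when the non-junction mate mapped
                # (the aligner recorded the pair as a singleton); a junction
                # is in 'pe' mode in a sample when any such pair exists
                n_pe = sum(1 for rid in pairs if mode_by_read.get(rid) == "se")
                pe_se.loc[jid, sample] = "pe" if n_pe >= 1 else "se"
    return JunctionCountMatrix(counts, samples, pe_se, intervals)


# ---------------------------------------------------------------------------
# cascade steps


def filter_pe_consistency(
    m: JunctionCountMatrix, report: FilterReport | None = None
) -> JunctionCountMatrix:
    """Remove junctions whose untreated/treated samples of any biological
    replicate disagree in pe/se mapping mode."""
    if m.pe_se is None:
        raise FilterError("pe/se status not populated")
    keep = []
    groups = m.samples.groupby(["species", "tissue", "replicate"])
    for jid in m.junction_ids:
        ok = True
        for _, grp in groups:
            modes = {}
            for sid, row in grp.iterrows():
                mode = m.pe_se.loc[jid, sid]
                if isinstance(mode, str):  # None/NaN: junction absent here
                    modes[row["condition"]] = mode
            if len(modes) == 2 and modes["untreated"] != modes["treated"]:
                ok = False
                break
        if ok:
            keep.append(jid)
    if report is not None:
        report.add("pe_consistency", len(m.junction_ids),
                   len(m.junction_ids) - len(keep))
    return m.subset(keep)


def filter_untreated_presence(
    m: JunctionCountMatrix, report: FilterReport | None = None
) -> JunctionCountMatrix:
    """Keep junctions with at least one read in at least one untreated
    replicate."""
    untreated = m.samples.index[m.samples["condition"] == "untreated"]
    keep = m.counts.index[(m.counts[untreated] >= 1).any(axis=1)]
    if report is not None:
        report.add("untreated_presence", len(m.junction_ids),
                   len(m.junction_ids) - len(keep))
    return m.subset(keep)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors from junctions common to all samples.

    Per common junction (nonzero everywhere), the geometric mean across
    samples is taken; a sample's factor is the median over junctions of
    count / geometric mean.  Factors carry an arbitrary common scale:
    scaling any one sample's counts by a constant scales its factor
    relative to every other sample by exactly that constant.
    """
    common = counts.loc[(counts > 0).all(axis=1)]
    if common.empty:
        raise FilterError(
            "no junctions are nonzero in all samples; relax the sample set"
        )
    log_gm = np.log(common).mean(axis=1)
    ratios = np.exp(np.log(common).sub(log_gm, axis=0))
    return ratios.median(axis=0)


def filter_enrichment(
    m: JunctionCountMatrix,
    factors: pd.Series,
    min_log2: float = DEFAULT_MIN_LOG2_ENRICHMENT,
    report: FilterReport | None = None,
) -> JunctionCountMatrix:
    """Keep junctions with log2(treated/untreated) >= ``min_log2`` on
    size-factor-normalized mean counts, pooling a species' samples within
    each condition."""
    norm = m.counts.div(factors.loc[m.counts.columns], axis=1)
    keep = []
    for jid in m.junction_ids:
        ok = False
        for _, grp in m.samples.groupby("species"):
            u_cols = grp.index[grp["condition"] == "untreated"]
            t_cols = grp.index[grp["condition"] == "treated"]
            u_mean = norm.loc[jid, u_cols].mean()
            t_mean = norm.loc[jid, t_cols].mean()
            if u_mean == 0:
                # cannot occur after the untreated-presence step
                assert m.counts.loc[jid, u_cols].sum() == 0
                continue
            if t_mean > 0 and np.log2(t_mean / u_mean) >= min_log2:
                ok = True
        if ok:
            keep.append(jid)
    if report is not None:
        report.add("rnase_r_enrichment", len(m.junction_ids),
                   len(m.junction_ids) - len(keep))
    return m.subset(keep)


def tissue_cpm(m: JunctionCountMatrix, condition: str = "untreated") -> pd.DataFrame:
    """Per-junction, per-tissue CPM: replicate-averaged counts scaled by
    replicate-averaged mapped totals (generalized to any replicate count)."""
    sel = m.samples[m.samples["condition"] == condition]
    out = {}
    for (species, tissue), grp in sel.groupby(["species", "tissue"]):
        mean_mapped = grp["mapped_reads"].mean()
        if mean_mapped == 0:
            raise FilterError(f"zero mapped reads for {species}/{tissue}")
        mean_counts = m.counts[grp.index].mean(axis=1)
        out[(species, tissue)] = mean_counts * 1e6 / mean_mapped
    return pd.DataFrame(out)


def cpm_filter(
    m: JunctionCountMatrix,
    min_cpm: float = DEFAULT_MIN_CPM,
    report: FilterReport | None = None,
    condition: str = "untreated",
) -> tuple[JunctionCountMatrix, pd.DataFrame]:
    """Keep junctions reaching ``min_cpm`` (inclusive) in at least one
    tissue; returns the filtered matrix and the per-tissue CPM table."""
    cpm = tissue_cpm(m, condition)
    keep = cpm.index[(cpm >= min_cpm).any(axis=1)]
    if report is not None:
        report.add("min_cpm", len(m.junction_ids), len(m.junction_ids) - len(keep))
    return m.subset(keep), cpm.loc[keep]


def read_blacklist(path) -> list[tuple[str, GenomicInterval]]:
    """Blacklist TSV: species, chrom, start, end, strand (0-based half-open)."""
    df = pd.read_csv(path, sep="\t")
    return [
        (r.species, GenomicInterval(str(r.chrom), int(r.start), int(r.end), r.strand))
        for r in df.itertuples()
    ]


def default_blacklist() -> list[tuple[str, GenomicInterval]]:
    """The manually curated repetitive testis regions shipped as a fixture."""
    ref = importlib.resources.files("circevo") / "data" / "blacklist_regions.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_blacklist(path)


def blacklist_filter(
    m: JunctionCountMatrix,
    regions: list[tuple[str, GenomicInterval]],
    species: str | None = None,
    report: FilterReport | None = None,
) -> JunctionCountMatrix:
    """Remove junctions overlapping (by any amount) a same-species
    blacklisted region."""
    keep = []
    for jid in m.junction_ids:
        iv = m.intervals.get(jid)
        hit = False
        if iv is not None:
            for sp, region in regions:
                if species is not None and sp != species:
                    continue
                if iv.overlap(region) > 0:
                    hit = True
                    break
        if not hit:
            keep.append(jid)
    if report is not None:
        report.add("blacklist", len(m.junction_ids),
                   len(m.junction_ids) - len(keep))
    return m.subset(keep)


def run_cascade(
    m: JunctionCountMatrix,
    factors: pd.Series,
    min_log2: float = DEFAULT_MIN_LOG2_ENRICHMENT,
    min_cpm: float = DEFAULT_MIN_CPM,
    blacklist: list[tuple[str, GenomicInterval]] | None = None,
    species: str | None = None,
) -> tuple[JunctionCountMatrix, pd.DataFrame, FilterReport]:
    """The ordered four-step cascade plus optional blacklisting."""
    report = FilterReport()
    m = filter_pe_consistency(m, report)
    m = filter_untreated_presence(m, report)
    m = filter_enrichment(m, factors, min_log2, report)
    m, cpm = cpm_filter(m, min_cpm, report)
    if blacklist is not None:
        m = blacklist_filter(m, blacklist, species, report)
        cpm = cpm.loc[m.junction_ids]
    assert report.telescopes()
    return m, cpm, report
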