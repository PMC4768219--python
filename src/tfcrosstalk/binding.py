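"""HSF1 peak handling: regulatory windows, peak assignment, peak calling and
the per-gene heat-shock-induced-binding verdict.

The regulatory window of a gene spans 7500 bp upstream to 2500 bp downstream
of the TSS, oriented by strand and clipped at the chromosome start.  Peaks
are BED6-style intervals (0-based, half-open); a peak is assigned to every
gene whose window it overlaps by at least one base.  Induction at a heat-shock
timepoint (10 or 20 min) is called per gene by comparing the strongest HS peak
in the window with the control signal; a gene is "HS-induced" when either
timepoint is significant (union rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DegenerateDataError, InputError

logger = logging.getLogger(__name__)

UPSTREAM_BP = 7500
DOWNSTREAM_BP = 2500
BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

#: BED-only induction rule: HS peak must beat the control window signal by
#: this score factor (or have no control counterpart at all).
DEFAULT_SCORE_RATIO = 2.0

TIMEPOINTS = ("HS_10", "HS_20")
CONTROL_CONDITION = "Ctr"


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval."""

    chrom: str
    start: int
    end: int
    strand: str | None = None
    score: float | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise InputError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


def read_bed(path) -> pd.DataFrame:
    peaks = pd.read_csv(path, sep="\t", header=None, comment="#")
    peaks = peaks.iloc[:, : len(BED_COLUMNS)]
    peaks.columns = BED_COLUMNS[: peaks.shape[1]]
    for col, default in (("name", "."), ("score", 0.0), ("strand", ".")):
        if col not in peaks.columns:
            peaks[col] = default
    return peaks


def write_bed(peaks: pd.DataFrame, path) -> None:
    peaks[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False, float_format="%.4f")


# --------------------------------------------------------------------------
# Regulatory windows
# --------------------------------------------------------------------------

def make_window(
    chrom: str,
    tss: int,
    strand: str,
    upstream: int = UPSTREAM_BP,
    downstream: int = DOWNSTREAM_BP,
) -> GenomicInterval:
    """Strand-aware regulatory window around one TSS, clipped at position 0."""
    if strand == "+":
        start, end = tss - upstream, tss + downstream
    elif strand == "-":
        start, end = tss - downstream, tss + upstream
    else:
        raise InputError(f"strand must be '+' or '-', got {strand!r}")
    return GenomicInterval(chrom, max(0, start), end, strand=strand)


def windows_table(
    annotation: pd.DataFrame,
    upstream: int = UPSTREAM_BP,
    downstream: int = DOWNSTREAM_BP,
) -> pd.DataFrame:
    """Regulatory windows for an annotation table (gene_id, chrom, tss, strand).

    Genes listed with multiple TSS keep their single 5'-most TSS.
    """
    required = {"gene_id", "chrom", "tss", "strand"}
    if not required.issubset(annotation.columns):
        raise InputError(f"annotation needs columns {sorted(required)}")
    ann = annotation.copy()
    if ann["gene_id"].duplicated().any():
        # 5'-most TSS: minimal tss on '+', maximal on '-'
        logger.info("annotation has duplicate gene ids; keeping the 5'-most TSS per gene")
        ann["_key"] = np.where(ann["strand"] == "+", ann["tss"], -ann["tss"])
        ann = ann.sort_values("_key").drop_duplicates("gene_id").drop(columns="_key")
    rows = []
    for rec in ann.itertuples(index=False):
        win = make_window(rec.chrom, int(rec.tss), rec.strand, upstream, downstream)
        rows.append((rec.gene_id, win.chrom, win.start, win.end, rec.strand))
    out = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return out.sort_values("gene_id", kind="mergesort").reset_index(drop=True)


# --------------------------------------------------------------------------
# Peak assignment
# --------------------------------------------------------------------------

def assign_peaks(peaks: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Assign every peak to every gene whose window it overlaps (≥1 bp).

    Returns one row per (gene, peak) pair, sorted by gene then peak start.
    Chromosomes present on only one side contribute no assignments (logged).
    """
    for frame, label in ((peaks, "peaks"), (windows, "windows")):
        if not {"chrom", "start", "end"}.issubset(frame.columns):
            raise InputError(f"{label} need chrom/start/end columns")
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in windows.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), g) for g, s, e in zip(grp["gene_id"], grp["start"], grp["end"])
        )
    missing = set(peaks["chrom"].unique()) - set(trees)
    if missing:
        logger.warning("peak chromosomes absent from windows (no overlap): %s", sorted(missing))
    rows = []
    for idx, rec in enumerate(peaks.itertuples(index=False)):
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(int(rec.start), int(rec.end)):
            rows.append(
                (
                    hit.data,
                    idx,
                    rec.chrom,
                    int(rec.start),
                    int(rec.end),
                    getattr(rec, "name", "."),
                    float(getattr(rec, "score", 0.0)),
                )
            )
    out = pd.DataFrame(
        rows, columns=["gene_id", "peak_index", "chrom", "start", "end", "peak_name", "score"]
    )
    return out.sort_values(["gene_id", "start", "end"], kind="mergesort").reset_index(drop=True)


# --------------------------------------------------------------------------
# Simple Poisson peak caller (tag tracks vs input reference)
# --------------------------------------------------------------------------

def call_peaks_simple(track: pd.DataFrame, reference: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Call enriched bins of a tag track against a reference (input) track.

    Both tracks are fixed-width bin tables (chrom, start, count) on the same
    grid.  Per bin the Poisson upper tail P[X ≥ c] is taken at λ equal to the
    depth-scaled reference count, floored at the depth-scaled global reference
    rate; BH correction across bins at level ``fdr``; adjacent significant
    bins merge into peaks scored by −log10 of the best adjusted p.
    """
    if not 0 < fdr < 1:
        raise ConfigurationError("fdr must lie in (0, 1)")
    for frame, label in ((track, "track"), (reference, "reference")):
        if not {"chrom", "start", "count"}.issubset(frame.columns):
            raise InputError(f"{label} needs chrom/start/count columns")
    if len(track) != len(reference) or not (
        track["start"].to_numpy() == reference["start"].to_numpy()
    ).all():
        raise InputError("track and reference must share one bin grid")
    ref = reference["count"].to_numpy(dtype=float)
    obs = track["count"].to_numpy(dtype=float)
    ref_total = ref.sum()
    if ref_total <= 0:
        raise DegenerateDataError("reference track has zero depth")
    scale = obs.sum() / ref_total
    lam = np.maximum(scale * ref, scale * ref.mean())
    p = stats.poisson.sf(obs - 1, lam)
    significant, p_adj = multipletests(p, alpha=fdr, method="fdr_bh")[:2]
    bin_width = _bin_width(track)
    peaks = []
    i, n = 0, len(track)
    chroms = track["chrom"].to_numpy()
    starts = track["start"].to_numpy()
    while i < n:
        if not significant[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and significant[j + 1]
            and chroms[j + 1] == chroms[j]
            and starts[j + 1] == starts[j] + bin_width
        ):
            j += 1
        best = p_adj[i : j + 1].min()
        score = -np.log10(max(best, 1e-300))
        peaks.append(
            (chroms[i], int(starts[i]), int(starts[j]) + bin_width, f"peak_{len(peaks) + 1}", score, ".")
        )
        i = j + 1
    return pd.DataFrame(peaks, columns=BED_COLUMNS)


def _bin_width(track: pd.DataFrame) -> int:
    starts = np.sort(track["start"].unique())
    if starts.size < 2:
        return int(track.get("end", track["start"] + 1).iloc[0] - track["start"].iloc[0]) or 1
    return int(np.diff(starts).min())


# --------------------------------------------------------------------------
# Induced-binding calls
# --------------------------------------------------------------------------

def call_induced_binding(
    peaks_by_condition: Mapping[str, pd.DataFrame],
    windows: pd.DataFrame,
    fdr: float = 0.05,
    score_ratio: float = DEFAULT_SCORE_RATIO,
    tracks_by_condition: Mapping[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Per-gene HSF1 induction verdict from the 10- and 20-min heat-shock peaks.

    BED-only route: a gene is induced at a timepoint when its window holds an
    HS peak and the best HS peak score exceeds ``score_ratio`` times the best
    control peak score in the window (trivially satisfied when control has no
    peak there).  With tag tracks supplied, window tag counts are compared by
    a depth-scaled Poisson test, BH-corrected across genes at ``fdr``.
    ``induced_any`` is the union over the two timepoints.
    """
    needed = set(TIMEPOINTS) | {CONTROL_CONDITION}
    missing = needed - set(peaks_by_condition)
    if missing:
        raise ConfigurationError(f"missing peak sets for conditions: {sorted(missing)}")
    gene_ids = windows["gene_id"].tolist()
    best = {}
    support = {}
    for cond in needed:
        assigned = assign_peaks(peaks_by_condition[cond], windows)
        if assigned.empty:
            best[cond] = pd.Series(0.0, index=gene_ids)
            support[cond] = {}
        else:
            best[cond] = (
                assigned.groupby("gene_id")["score"].max().reindex(gene_ids).fillna(0.0)
            )
            support[cond] = {
                g: ",".join(grp["peak_name"].astype(str))
                for g, grp in assigned.groupby("gene_id")
            }
    out = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    out["bound_ctr"] = best[CONTROL_CONDITION].to_numpy() > 0
    if tracks_by_condition is not None:
        induced = _induced_from_tracks(tracks_by_condition, windows, fdr)
    else:
        induced = {}
        ctr = best[CONTROL_CONDITION].to_numpy()
        for tp in TIMEPOINTS:
            hs = best[tp].to_numpy()
            induced[tp] = (hs > 0) & (hs >= score_ratio * ctr) & (hs > ctr)
    out["induced_hs10"] = induced["HS_10"]
    out["induced_hs20"] = induced["HS_20"]
    out["induced_any"] = out["induced_hs10"] | out["induced_hs20"]
    out["supporting_peaks"] = [
        ";".join(
            f"{tp}:{support[tp][g]}" for tp in TIMEPOINTS if g in support[tp]
        )
        for g in gene_ids
    ]
    return out.reset_index()


def _window_counts(track: pd.DataFrame, windows: pd.DataFrame) -> np.ndarray:
    """Total tag count of each window, from a binned track."""
    width = _bin_width(track)
    counts = np.zeros(len(windows))
    by_chrom = {c: grp for c, grp in track.groupby("chrom")}
    for i, rec in enumerate(windows.itertuples(index=False)):
        grp = by_chrom.get(rec.chrom)
        if grp is None:
            continue
        starts = grp["start"].to_numpy()
        mask = (starts + width > rec.start) & (starts < rec.end)
        counts[i] = grp["count"].to_numpy()[mask].sum()
    return counts


def _induced_from_tracks(tracks, windows, fdr):
    if CONTROL_CONDITION not in tracks:
        raise ConfigurationError("tag tracks need a control condition")
    ctr_counts = _window_counts(tracks[CONTROL_CONDITION], windows)
    ctr_depth = tracks[CONTROL_CONDITION]["count"].sum()
    if ctr_depth <= 0:
        raise DegenerateDataError("control track has zero depth")
    induced = {}
    for tp in TIMEPOINTS:
        if tp not in tracks:
            raise ConfigurationError(f"tag tracks missing condition {tp}")
        hs_counts = _window_counts(tracks[tp], windows)
        scale = tracks[tp]["count"].sum() / ctr_depth
        lam = np.maximum(scale * ctr_counts, 1e-8)
        p = stats.poisson.sf(hs_counts - 1, lam)
        sig = multipletests(p, alpha=fdr, method="fdr_bh")[0]
        induced[tp] = sig & (hs_counts > scale * ctr_counts)
    return induced
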