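"""Synthetic study generator with planted ground truth.

Emulates every data layer of a four-condition (Ctr / TNF / HS / HS_TNF)
cross-talk study on one synthetic chromosome: gene annotation, proximal
promoter sequences with planted κB/HSE motif instances, replicate log2
expression with planted regulation modes, per-condition HSF1 peak sets with
planted heat-shock-induced binding, and a flat gene→term annotation.  Every
planted fact is recorded in a :class:`GroundTruth` ledger so downstream
recovery can be scored exactly.

Expression effects are additive on the log2 scale.  Each gene draws one
regulation mode; the mode fixes the effect Δ of each condition relative to
the gene's baseline (e = ``effect_log2fc``):

=====================  =======  ===========  ==============
mode                   Δ_TNF    Δ_HS         Δ_HS_TNF
=====================  =======  ===========  ==============
null                   0        0            0
tnf_only_up            +e       0            +e
tnf_only_down          −e       0            −e
hs_only_up             0        +e           +e
hs_only_down           0        −e           −e
co_activated           +e       +e           +2e
co_repressed           −e       −e           −2e
suppressed_activation  +e       0 or −e      Δ_HS
relieved_repression    −e       0            0
=====================  =======  ===========  ==============

``suppressed_activation`` genes lose their cytokine activation entirely after
heat-shock pre-treatment; a configurable fraction of them is also repressed
by heat shock on its own, mirroring the observation that antagonized genes
are often HS-downregulated themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import motifs as motif_mod
from .binding import BED_COLUMNS, windows_table, write_bed
from .errors import ConfigurationError, SizingError
from .expression import CONDITIONS, ExpressionMatrix
from .motifs import PWM, build_hse_pwm, kb_pwm, reverse_complement

MODES = (
    "co_activated",
    "co_repressed",
    "suppressed_activation",
    "relieved_repression",
    "tnf_only_up",
    "tnf_only_down",
    "hs_only_up",
    "hs_only_down",
    "null",
)

TNF_MODES = (
    "co_activated",
    "co_repressed",
    "suppressed_activation",
    "relieved_repression",
    "tnf_only_up",
    "tnf_only_down",
)

#: planted mode → combined-effect mode the classifier should recover
EXPECTED_COMBINED_MODE = {
    "co_activated": "enhanced_activation",
    "co_repressed": "enhanced_repression",
    "suppressed_activation": "suppressed_activation",
    "relieved_repression": "relieved_repression",
    "tnf_only_up": "unaffected",
    "tnf_only_down": "unaffected",
}

PEAK_CONDITIONS = ("Ctr", "HS_10", "HS_20")


def _default_mode_fractions() -> dict:
    return {
        "co_activated": 0.03,
        "co_repressed": 0.02,
        "suppressed_activation": 0.04,
        "relieved_repression": 0.02,
        "tnf_only_up": 0.04,
        "tnf_only_down": 0.03,
        "hs_only_up": 0.06,
        "hs_only_down": 0.06,
        "null": 0.70,
    }


def _default_motif_probs() -> dict:
    # background rates echo genome-wide motif frequencies (~24 % κB, ~6 % HSE)
    return {
        "kb": {"tnf_modulated": 0.8, "background": 0.24},
        "hse": {"hs_modulated": 0.5, "background": 0.06},
    }


def _default_binding_probs() -> dict:
    # ~11 % of all genes gain HSF1 binding after HS; HS-modulated genes ~24 %
    return {"hs_modulated": 0.24, "background": 0.11}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    n_genes: int = 2000
    n_replicates_per_condition: int = 3
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.25
    effect_log2fc: float = 2.0
    mode_fractions: dict = field(default_factory=_default_mode_fractions)
    motif_plant_prob_by_class: dict = field(default_factory=_default_motif_probs)
    binding_plant_prob_by_class: dict = field(default_factory=_default_binding_probs)
    promoter_length: int = 1000
    background_composition: tuple = (0.25, 0.25, 0.25, 0.25)
    peak_width_range: tuple = (200, 800)
    tag_depth: float = 10.0
    tss_spacing: int = 25000
    tss_jitter: int = 2000
    chrom: str = "chrS1"
    chrom_margin: int = 20000
    chrom_length: int | None = None
    basal_peaks_per_gene: float = 1.0
    basal_score_mean: float = 30.0
    induced_score_factor: float = 5.0
    ctr_weak_peak_prob: float = 0.3
    suppressed_hs_down_prob: float = 0.55
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be >= 0")
        if self.n_replicates_per_condition < 2:
            raise ConfigurationError("need >= 2 replicates per condition")
        if self.promoter_length < 1000:
            raise ConfigurationError("promoter_length must be >= 1000")
        if self.baseline_sd < 0 or self.noise_sd < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        if self.effect_log2fc <= 0:
            raise ConfigurationError("effect_log2fc must be > 0")
        unknown = set(self.mode_fractions) - set(MODES)
        if unknown:
            raise ConfigurationError(f"unknown mode labels: {sorted(unknown)}")
        total = sum(self.mode_fractions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigurationError(f"mode_fractions must sum to 1, got {total}")
        lo, hi = self.peak_width_range
        if not 0 < lo <= hi:
            raise ConfigurationError("peak_width_range must be a positive interval")
        if self.tss_spacing <= 0 or self.tss_jitter < 0:
            raise ConfigurationError("spacing must be positive, jitter >= 0")

    def min_chrom_length(self) -> int:
        return 2 * self.chrom_margin + max(0, self.n_genes) * self.tss_spacing

    def resolved_chrom_length(self) -> int:
        need = self.min_chrom_length()
        if self.chrom_length is None:
            return need
        if self.chrom_length < need:
            raise SizingError(
                f"chromosome of {self.chrom_length} bp cannot hold {self.n_genes} genes "
                f"at spacing {self.tss_spacing} (need >= {need})"
            )
        return self.chrom_length


class GroundTruth:
    """Per-gene ledger of everything the generator planted."""

    def __init__(self, genes: pd.DataFrame, peaks: pd.DataFrame | None = None):
        if genes["gene_id"].duplicated().any():
            raise ConfigurationError("ground truth must list every gene exactly once")
        self.genes = genes.reset_index(drop=True)
        self.peaks = peaks if peaks is not None else pd.DataFrame(columns=BED_COLUMNS + ["gene_id", "condition"])

    def expected_call(self, contrast_name: str) -> pd.Series:
        """Noise-free DE call per gene for a named default contrast."""
        key = {
            "tnf_vs_ctr": "delta_tnf",
            "hs_vs_ctr": "delta_hs",
            "hstnf_vs_tnf": None,
            "hstnf_vs_hs": None,
        }
        if contrast_name not in key:
            raise ConfigurationError(f"unknown contrast {contrast_name!r}")
        if contrast_name == "hstnf_vs_tnf":
            delta = self.genes["delta_hstnf"] - self.genes["delta_tnf"]
        elif contrast_name == "hstnf_vs_hs":
            delta = self.genes["delta_hstnf"] - self.genes["delta_hs"]
        else:
            delta = self.genes[key[contrast_name]]
        ratio = np.exp2(delta)
        call = np.where(ratio > 1.2, "up", np.where(ratio < 0.8, "down", "none"))
        return pd.Series(call, index=self.genes["gene_id"], name=contrast_name)

    def expected_mode(self) -> pd.Series:
        """Combined-effect mode the classifier should assign ('' outside TNF)."""
        out = self.genes["mode"].map(EXPECTED_COMBINED_MODE).fillna("")
        out.index = self.genes["gene_id"]
        return out

    def to_tsv(self, path) -> None:
        self.genes.to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path, peaks: pd.DataFrame | None = None) -> "GroundTruth":
        return cls(pd.read_csv(path, sep="\t"), peaks)


# --------------------------------------------------------------------------
# Stage generators
# --------------------------------------------------------------------------

def simulate_annotation(cfg: SimulationConfig) -> pd.DataFrame:
    """Gene anchors on one synthetic chromosome, TSS on a jittered grid.

    Pairwise TSS distances are at least ``tss_spacing − tss_jitter``, so with
    spacing comfortably above the regulatory window span adjacent windows do
    not overlap.
    """
    cfg.validate()
    cfg.resolved_chrom_length()
    rng = np.random.default_rng(cfg.rng_seed)
    n = cfg.n_genes
    tss = cfg.chrom_margin + np.arange(n) * cfg.tss_spacing
    if cfg.tss_jitter > 0 and n:
        tss = tss + rng.integers(0, cfg.tss_jitter + 1, size=n)
    strand = rng.choice(["+", "-"], size=n)
    return pd.DataFrame(
        {
            "gene_id": [f"G{i + 1:06d}" for i in range(n)],
            "chrom": cfg.chrom,
            "tss": tss.astype(int) if n else pd.Series([], dtype=int),
            "strand": strand,
        }
    )


def _mode_deltas(mode: str, e: float, hs_down: bool) -> tuple[float, float, float]:
    table = {
        "null": (0.0, 0.0, 0.0),
        "tnf_only_up": (e, 0.0, e),
        "tnf_only_down": (-e, 0.0, -e),
        "hs_only_up": (0.0, e, e),
        "hs_only_down": (0.0, -e, -e),
        "co_activated": (e, e, 2 * e),
        "co_repressed": (-e, -e, -2 * e),
        "relieved_repression": (-e, 0.0, 0.0),
    }
    if mode in table:
        return table[mode]
    if mode == "suppressed_activation":
        d_hs = -e if hs_down else 0.0
        return (e, d_hs, d_hs)
    raise ConfigurationError(f"unknown regulation mode {mode!r}")


def build_truth(cfg: SimulationConfig, annotation: pd.DataFrame | None = None) -> GroundTruth:
    """Draw modes, expression effects, motif plants and binding flags."""
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 1]))
    n = cfg.n_genes
    if annotation is None:
        annotation = simulate_annotation(cfg)
    labels = list(cfg.mode_fractions)
    probs = np.array([cfg.mode_fractions[m] for m in labels])
    modes = rng.choice(labels, size=n, p=probs / probs.sum())
    e = cfg.effect_log2fc
    hs_down = rng.random(n) < cfg.suppressed_hs_down_prob
    deltas = np.array([_mode_deltas(m, e, h) for m, h in zip(modes, hs_down)])
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n)
    tnf_mod = np.isin(modes, TNF_MODES)
    hs_mod = np.abs(deltas[:, 1]) > 0 if n else np.zeros(0, dtype=bool)
    kb_probs = cfg.motif_plant_prob_by_class["kb"]
    hse_probs = cfg.motif_plant_prob_by_class["hse"]
    kb_p = np.where(tnf_mod, kb_probs["tnf_modulated"], kb_probs["background"])
    hse_p = np.where(hs_mod, hse_probs["hs_modulated"], hse_probs["background"])
    kb_planted = rng.random(n) < kb_p
    hse_planted = rng.random(n) < hse_p
    bind = cfg.binding_plant_prob_by_class
    bind_p = np.where(hs_mod, bind["hs_modulated"], bind["background"])
    binding_induced = rng.random(n) < bind_p
    genes = annotation.copy()
    genes["mode"] = modes
    genes["baseline"] = baseline
    genes["delta_tnf"] = deltas[:, 0] if n else pd.Series([], dtype=float)
    genes["delta_hs"] = deltas[:, 1] if n else pd.Series([], dtype=float)
    genes["delta_hstnf"] = deltas[:, 2] if n else pd.Series([], dtype=float)
    genes["kb_planted"] = kb_planted
    genes["hse_planted"] = hse_planted
    genes["binding_induced"] = binding_induced
    return GroundTruth(genes)


def simulate_expression(cfg: SimulationConfig, truth: GroundTruth) -> ExpressionMatrix:
    """Replicate log2 intensities: baseline + mode effect + N(0, noise_sd)."""
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 2]))
    R = cfg.n_replicates_per_condition
    g = truth.genes
    delta = {
        "Ctr": np.zeros(len(g)),
        "TNF": g["delta_tnf"].to_numpy(),
        "HS": g["delta_hs"].to_numpy(),
        "HS_TNF": g["delta_hstnf"].to_numpy(),
    }
    cols, names, conds = [], [], {}
    for cond in CONDITIONS:
        mean = g["baseline"].to_numpy() + delta[cond]
        for r in range(1, R + 1):
            noise = rng.normal(0.0, cfg.noise_sd, size=len(g)) if cfg.noise_sd > 0 else 0.0
            cols.append(mean + noise)
            name = f"{cond}_{r}"
            names.append(name)
            conds[name] = cond
    values = pd.DataFrame(
        np.column_stack(cols) if cols else np.empty((len(g), 0)),
        index=pd.Index(g["gene_id"], name="gene_id"),
        columns=names,
    )
    return ExpressionMatrix(values, conds)


def simulate_promoters(
    cfg: SimulationConfig, truth: GroundTruth, pwms: dict[str, PWM] | None = None
) -> dict[str, str]:
    """Promoter sequences: i.i.d. background with planted consensus instances.

    For genes flagged in the truth ledger one consensus instance per motif is
    inserted at a recorded offset on a recorded strand; κB and HSE plants in
    the same promoter never overlap.  The truth ledger gains
    ``{kb,hse}_offset`` / ``{kb,hse}_strand`` columns (offset −1 = no plant).
    """
    cfg.validate()
    if pwms is None:
        pwms = {"kb": kb_pwm(), "hse": build_hse_pwm(3)}
    for key, pwm in pwms.items():
        if pwm.width > cfg.promoter_length:
            raise SizingError(f"promoter of {cfg.promoter_length} bp shorter than motif {key}")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 3]))
    bases = np.array(list("ACGT"))
    comp = np.asarray(cfg.background_composition, dtype=float)
    comp = comp / comp.sum()
    seqs: dict[str, str] = {}
    offsets = {k: [] for k in pwms}
    strands = {k: [] for k in pwms}
    L = cfg.promoter_length
    for rec in truth.genes.itertuples(index=False):
        seq = rng.choice(bases, size=L, p=comp)
        occupied: list[tuple[int, int]] = []
        for key, pwm in pwms.items():
            planted = getattr(rec, f"{key}_planted", False)
            if not planted:
                offsets[key].append(-1)
                strands[key].append(".")
                continue
            w = pwm.width
            for _ in range(200):
                off = int(rng.integers(0, L - w + 1))
                if all(off + w <= s or off >= e for s, e in occupied):
                    break
            occupied.append((off, off + w))
            strand = "+" if rng.random() < 0.5 else "-"
            inst = pwm.consensus if strand == "+" else reverse_complement(pwm.consensus)
            seq[off : off + pwm.width] = list(inst)
            offsets[key].append(off)
            strands[key].append(strand)
        seqs[rec.gene_id] = "".join(seq)
    for key in pwms:
        truth.genes[f"{key}_offset"] = offsets[key]
        truth.genes[f"{key}_strand"] = strands[key]
    return seqs


def simulate_binding(
    cfg: SimulationConfig, truth: GroundTruth, annotation: pd.DataFrame | None = None
) -> dict[str, pd.DataFrame]:
    """Per-condition HSF1 peak sets (BED6 frames) with planted induction.

    Basal peaks are placed uniformly on the chromosome, independent of the
    truth, and appear in all three conditions with jittered scores.  Each
    ``binding_induced`` gene receives an extra strong peak inside its
    regulatory window in HS_10 and HS_20; the control either lacks it or
    carries a much weaker one.
    """
    cfg.validate()
    if annotation is None:
        annotation = truth.genes[["gene_id", "chrom", "tss", "strand"]]
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 4]))
    chrom_len = cfg.resolved_chrom_length()
    lo, hi = cfg.peak_width_range
    n_basal = int(round(cfg.basal_peaks_per_gene * cfg.n_genes))
    basal_width = rng.integers(lo, hi + 1, size=n_basal)
    basal_start = rng.integers(0, max(1, chrom_len - hi), size=n_basal)
    basal_score = rng.gamma(shape=8.0, scale=cfg.basal_score_mean / 8.0, size=n_basal)
    windows = windows_table(annotation)
    win_by_gene = windows.set_index("gene_id")
    peaks = {cond: [] for cond in PEAK_CONDITIONS}
    for i in range(n_basal):
        for cond in PEAK_CONDITIONS:
            jitter = rng.uniform(0.8, 1.25)
            peaks[cond].append(
                (
                    cfg.chrom,
                    int(basal_start[i]),
                    int(basal_start[i] + basal_width[i]),
                    f"basal_{i + 1}",
                    float(basal_score[i] * jitter),
                    ".",
                )
            )
    planted_rows = []
    induced_score = cfg.induced_score_factor * cfg.basal_score_mean
    for rec in truth.genes.itertuples(index=False):
        if not rec.binding_induced:
            continue
        win = win_by_gene.loc[rec.gene_id]
        width = int(rng.integers(lo, hi + 1))
        upper = max(int(win["start"]) + 1, int(win["end"]) - width)
        start = int(rng.integers(int(win["start"]), upper))
        end = min(start + width, chrom_len)
        name = f"induced_{rec.gene_id}"
        score = float(induced_score * rng.uniform(0.8, 1.2))
        for cond in ("HS_10", "HS_20"):
            peaks[cond].append((cfg.chrom, start, end, name, score * rng.uniform(0.9, 1.1), "."))
        if rng.random() < cfg.ctr_weak_peak_prob:
            peaks["Ctr"].append(
                (cfg.chrom, start, end, name + "_weak", float(cfg.basal_score_mean), ".")
            )
        planted_rows.append((cfg.chrom, start, end, name, score, ".", rec.gene_id, "HS"))
    out = {}
    for cond in PEAK_CONDITIONS:
        frame = pd.DataFrame(peaks[cond], columns=BED_COLUMNS)
        out[cond] = frame.sort_values(["start", "end"], kind="mergesort").reset_index(drop=True)
    truth.peaks = pd.DataFrame(planted_rows, columns=BED_COLUMNS + ["gene_id", "condition"])
    return out


def simulate_tag_tracks(
    cfg: SimulationConfig,
    peaks_by_condition: dict[str, pd.DataFrame],
    bin_width: int = 100,
) -> dict[str, pd.DataFrame]:
    """Binned tag-count tracks consistent with the peak sets, plus an input
    reference: Poisson background at ``tag_depth`` per bin everywhere and
    additional score-proportional signal over each peak footprint."""
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 5]))
    chrom_len = cfg.resolved_chrom_length()
    starts = np.arange(0, chrom_len, bin_width)
    tracks = {}
    grid = pd.DataFrame({"chrom": cfg.chrom, "start": starts})
    tracks["input"] = grid.assign(count=rng.poisson(cfg.tag_depth, size=starts.size))
    for cond, frame in peaks_by_condition.items():
        lam = np.full(starts.size, float(cfg.tag_depth))
        for rec in frame.itertuples(index=False):
            i0, i1 = rec.start // bin_width, max(rec.start // bin_width + 1, -(-rec.end // bin_width))
            # excess tag rate per bin ~ score/2: basal peaks pile up a few-fold
            # over input, induced peaks several-fold higher still
            lam[i0:i1] += float(rec.score) / 2.0
        tracks[cond] = grid.assign(count=rng.poisson(lam))
    return tracks


def simulate_terms(
    cfg: SimulationConfig,
    truth: GroundTruth,
    n_random_terms: int = 20,
    planted_prob: float = 0.6,
    background_prob: float = 0.05,
) -> pd.DataFrame:
    """Flat gene→term annotation with one planted term per planted gene class
    (TNF-modulated, HS-modulated) plus random background terms."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 6]))
    g = truth.genes
    tnf_mod = g["mode"].isin(TNF_MODES).to_numpy()
    hs_mod = (g["delta_hs"].abs() > 0).to_numpy()
    rows = []
    for term, mask, label in (
        ("T_TNF_RESPONSE", tnf_mod, "planted: cytokine response"),
        ("T_HS_RESPONSE", hs_mod, "planted: heat-shock response"),
    ):
        p = np.where(mask, planted_prob, background_prob)
        take = rng.random(len(g)) < p
        rows += [(gid, term, label) for gid in g.loc[take, "gene_id"]]
    for t in range(n_random_terms):
        take = rng.random(len(g)) < background_prob
        rows += [(gid, f"T_RND_{t + 1:03d}", "random background term") for gid in g.loc[take, "gene_id"]]
    return pd.DataFrame(rows, columns=["gene_id", "term_id", "term_label"])


# --------------------------------------------------------------------------
# Whole-study convenience wrapper
# --------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    config: SimulationConfig
    annotation: pd.DataFrame
    truth: GroundTruth
    expression: ExpressionMatrix
    promoters: dict
    pwms: dict
    peaks: dict
    terms: pd.DataFrame

    def write(self, outdir) -> dict:
        """Write every artifact as plain text; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "annotation": outdir / "annotation.tsv",
            "expression": outdir / "expression.tsv",
            "sample_map": outdir / "sample_map.tsv",
            "promoters": outdir / "promoters.fasta",
            "pwms": outdir / "motifs.jaspar",
            "terms": outdir / "terms.tsv",
            "truth": outdir / "truth.tsv",
        }
        self.annotation.to_csv(paths["annotation"], sep="\t", index=False)
        self.expression.to_tsv(paths["expression"], paths["sample_map"])
        records = [
            SeqRecord(Seq(self.promoters[g]), id=g, description="")
            for g in self.annotation["gene_id"]
        ]
        SeqIO.write(records, str(paths["promoters"]), "fasta")
        motif_mod.write_jaspar(self.pwms.values(), paths["pwms"])
        self.terms.to_csv(paths["terms"], sep="\t", index=False)
        self.truth.to_tsv(paths["truth"])
        for cond, frame in self.peaks.items():
            p = outdir / f"peaks_{cond}.bed"
            write_bed(frame, p)
            paths[f"peaks_{cond}"] = p
        return paths


def simulate_study(cfg: SimulationConfig, pwms: dict[str, PWM] | None = None) -> SimulatedStudy:
    """Run every generator stage with one seed; deterministic per config."""
    cfg.validate()
    if pwms is None:
        pwms = {"kb": kb_pwm(), "hse": build_hse_pwm(3)}
    annotation = simulate_annotation(cfg)
    truth = build_truth(cfg, annotation)
    expression = simulate_expression(cfg, truth)
    promoters = simulate_promoters(cfg, truth, pwms)
    peaks = simulate_binding(cfg, truth, annotation)
    terms = simulate_terms(cfg, truth)
    return SimulatedStudy(cfg, annotation, truth, expression, promoters, pwms, peaks, terms)


# --------------------------------------------------------------------------
# Recovery scoring against the ledger
# --------------------------------------------------------------------------

def score_de_recovery(de_tables: dict, truth: GroundTruth) -> dict:
    """Pooled DE sensitivity and realized FDR over the given contrasts.

    A positive is any non-'none' call; a true positive additionally matches
    the planted direction.
    """
    tp = fp = fn = 0
    for name, table in de_tables.items():
        expected = truth.expected_call(name).reindex(table.index)
        called = table["call"].to_numpy()
        exp = expected.to_numpy()
        tp += int(((called != "none") & (called == exp)).sum())
        fp += int(((called != "none") & (exp == "none")).sum())
        fn += int(((exp != "none") & (called != exp)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    fdr = fp / (tp + fp) if tp + fp else 0.0
    return {"sensitivity": sens, "fdr": fdr, "tp": tp, "fp": fp, "fn": fn}


def score_mode_recovery(records: pd.DataFrame, truth: GroundTruth) -> dict:
    """Classification accuracy on planted TNF-involved genes."""
    expected = truth.expected_mode()
    planted = expected[expected != ""]
    got = records["mode"].reindex(planted.index).fillna("")
    correct = int((got.to_numpy() == planted.to_numpy()).sum())
    return {"accuracy": correct / len(planted) if len(planted) else float("nan"), "n": len(planted)}


def score_binding_recovery(binding: pd.DataFrame, truth: GroundTruth) -> dict:
    """Sensitivity / false-positive rate of the induced-binding verdict."""
    b = binding.set_index("gene_id") if "gene_id" in binding.columns else binding
    idx = truth.genes.set_index("gene_id").index
    called = b["induced_any"].reindex(idx).fillna(False).to_numpy()
    true = truth.genes.set_index("gene_id")["binding_induced"].to_numpy()
    tp = int((called & true).sum())
    fp = int((called & ~true).sum())
    sens = tp / true.sum() if true.sum() else float("nan")
    fpr = fp / (~true).sum() if (~true).sum() else 0.0
    return {"sensitivity": sens, "false_positive_rate": fpr, "n_induced": int(true.sum())}
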