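"""Combined-effect (interaction-mode) classification of TNF-modulated genes.

Heat-shock pre-treatment can change a gene's cytokine response four ways;
each TNF-modulated gene gets exactly one mode, decided by the same ratio+FDR
rule as primary DE calling applied to the HS_TNF-vs-TNF contrast:

* ``enhanced_activation``  — TNF-up gene, significantly increased further
  (co-activation when the gene is also HS-up on its own);
* ``suppressed_activation`` — TNF-up gene, significantly decreased
  (antagonistic effect of heat shock);
* ``enhanced_repression``  — TNF-down gene, significantly decreased further
  (co-repression when also HS-down);
* ``relieved_repression``  — TNF-down gene, significantly increased;
* ``unaffected``           — no significant change from the pre-treatment.

Report labels mirror the published table convention: ``A`` for co-activation
(enhanced activation of a gene that heat shock alone also upregulates) and
``O`` for the two antagonistic/opposite modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .expression import DEFAULT_THRESHOLDS

MODES = (
    "enhanced_activation",
    "enhanced_repression",
    "suppressed_activation",
    "relieved_repression",
    "unaffected",
)
CALLS = ("up", "down", "none")


def classify_mode(call_tnf: str, ratio_hstnf_vs_tnf: float, q_hstnf_vs_tnf: float,
                  thresholds=DEFAULT_THRESHOLDS) -> str:
    """Combined-effect mode of one TNF-modulated gene.

    ``call_tnf`` must be 'up' or 'down'; the ratio and q refer to the
    HS_TNF-vs-TNF contrast.
    """
    up_thr, down_thr, fdr = thresholds
    if call_tnf not in ("up", "down"):
        raise ConfigurationError("classify_mode requires a TNF-modulated gene (call up/down)")
    if not ratio_hstnf_vs_tnf > 0:
        raise InputError("ratio must be positive")
    significant_up = ratio_hstnf_vs_tnf > up_thr and q_hstnf_vs_tnf < fdr
    significant_down = ratio_hstnf_vs_tnf < down_thr and q_hstnf_vs_tnf < fdr
    if call_tnf == "up":
        if significant_up:
            return "enhanced_activation"
        if significant_down:
            return "suppressed_activation"
    else:
        if significant_down:
            return "enhanced_repression"
        if significant_up:
            return "relieved_repression"
    return "unaffected"


def flag_cofunctions(mode: str, call_hs: str) -> tuple[bool, bool]:
    """(coactivated, corepressed): enhanced modes backed by the same-direction
    response to heat shock alone."""
    coactivated = mode == "enhanced_activation" and call_hs == "up"
    corepressed = mode == "enhanced_repression" and call_hs == "down"
    return coactivated, corepressed


def table_label(mode: str, call_hs: str) -> str:
    """Published-table label: 'A' co-activation, 'O' antagonistic, '' otherwise."""
    if mode in ("suppressed_activation", "relieved_repression"):
        return "O"
    if flag_cofunctions(mode, call_hs)[0]:
        return "A"
    return ""


# --------------------------------------------------------------------------
# Record integration
# --------------------------------------------------------------------------

def build_records(
    de_tnf: pd.DataFrame,
    de_hs: pd.DataFrame,
    de_hstnf_vs_tnf: pd.DataFrame,
    motif_flags: pd.DataFrame | None = None,
    binding: pd.DataFrame | None = None,
    thresholds=DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """One integrated record per gene from three per-contrast DE tables plus
    optional motif flags (columns per motif name) and binding calls."""
    genes = de_tnf.index
    for other, label in ((de_hs, "HS"), (de_hstnf_vs_tnf, "HS_TNF-vs-TNF")):
        if not genes.equals(other.index):
            raise InputError(f"DE table for {label} is not aligned with TNF table")
    rec = pd.DataFrame(index=genes.copy())
    rec.index.name = "gene_id"
    rec["call_tnf"] = de_tnf["call"].to_numpy()
    rec["call_hs"] = de_hs["call"].to_numpy()
    rec["call_hstnf_vs_tnf"] = de_hstnf_vs_tnf["call"].to_numpy()
    rec["ratio_hstnf_vs_tnf"] = de_hstnf_vs_tnf["ratio"].to_numpy()
    rec["q_hstnf_vs_tnf"] = de_hstnf_vs_tnf["q"].to_numpy()
    modes = []
    for call_tnf, ratio, q in zip(
        rec["call_tnf"], rec["ratio_hstnf_vs_tnf"], rec["q_hstnf_vs_tnf"]
    ):
        if call_tnf == "none":
            modes.append("")
        else:
            modes.append(classify_mode(call_tnf, ratio, q, thresholds))
    rec["mode"] = modes
    co = [flag_cofunctions(m, h) if m else (False, False) for m, h in zip(rec["mode"], rec["call_hs"])]
    rec["coactivated"] = [c[0] for c in co]
    rec["corepressed"] = [c[1] for c in co]
    rec["table_label"] = [table_label(m, h) if m else "" for m, h in zip(rec["mode"], rec["call_hs"])]
    if motif_flags is not None:
        for motif in motif_flags.columns:
            key = "kb_motif" if "kb" in motif.lower() else (
                "hse_motif" if "hse" in motif.lower() else f"motif_{motif}"
            )
            rec[key] = motif_flags[motif].reindex(genes).fillna(False).to_numpy()
    for key in ("kb_motif", "hse_motif"):
        if key not in rec.columns:
            rec[key] = False
    if binding is not None:
        b = binding.set_index("gene_id") if "gene_id" in binding.columns else binding
        rec["hsf1_induced"] = b["induced_any"].reindex(genes).fillna(False).to_numpy()
    else:
        rec["hsf1_induced"] = False
    return rec


# --------------------------------------------------------------------------
# Tallies (figure-style counts)
# --------------------------------------------------------------------------

@dataclass
class SubsetTally:
    """Named counts of the gene subsets used throughout the analysis."""

    n_genes: int = 0
    tnf_modulated: int = 0
    tnf_up: int = 0
    tnf_down: int = 0
    hs_modulated: int = 0
    hs_up: int = 0
    hs_down: int = 0
    overlap: int = 0
    up_both: int = 0
    down_both: int = 0
    co_affected: int = 0
    mode_counts: dict = field(default_factory=dict)
    coactivated: int = 0
    corepressed: int = 0
    tnf_with_kb: int = 0
    tnf_with_hse: int = 0
    tnf_with_hsf1: int = 0
    tnf_up_kb_hsf1: int = 0
    kb_by_mode: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {k: v for k, v in self.__dict__.items() if not isinstance(v, dict)}
        out["mode_counts"] = dict(self.mode_counts)
        out["kb_by_mode"] = dict(self.kb_by_mode)
        return out


def tally_subsets(records: pd.DataFrame) -> SubsetTally:
    """Figure-style subset counts plus motif/binding intersections.

    Satisfies the partition identity: mode counts (including 'unaffected')
    sum to the number of TNF-modulated genes.
    """
    t = SubsetTally(n_genes=len(records))
    if records.empty:
        t.mode_counts = {m: 0 for m in MODES}
        t.kb_by_mode = {m: 0 for m in MODES}
        return t
    tnf_mod = records["call_tnf"] != "none"
    hs_mod = records["call_hs"] != "none"
    t.tnf_modulated = int(tnf_mod.sum())
    t.tnf_up = int((records["call_tnf"] == "up").sum())
    t.tnf_down = int((records["call_tnf"] == "down").sum())
    t.hs_modulated = int(hs_mod.sum())
    t.hs_up = int((records["call_hs"] == "up").sum())
    t.hs_down = int((records["call_hs"] == "down").sum())
    t.overlap = int((tnf_mod & hs_mod).sum())
    t.up_both = int(((records["call_tnf"] == "up") & (records["call_hs"] == "up")).sum())
    t.down_both = int(((records["call_tnf"] == "down") & (records["call_hs"] == "down")).sum())
    t.mode_counts = {m: int((records["mode"] == m).sum()) for m in MODES}
    t.co_affected = t.tnf_modulated - t.mode_counts["unaffected"]
    t.coactivated = int(records["coactivated"].sum())
    t.corepressed = int(records["corepressed"].sum())
    t.tnf_with_kb = int((tnf_mod & records["kb_motif"]).sum())
    t.tnf_with_hse = int((tnf_mod & records["hse_motif"]).sum())
    t.tnf_with_hsf1 = int((tnf_mod & records["hsf1_induced"]).sum())
    t.tnf_up_kb_hsf1 = int(
        ((records["call_tnf"] == "up") & records["kb_motif"] & records["hsf1_induced"]).sum()
    )
    t.kb_by_mode = {
        m: int(((records["mode"] == m) & records["kb_motif"]).sum()) for m in MODES
    }
    return t


# --------------------------------------------------------------------------
# Worked-example report
# --------------------------------------------------------------------------

_HS_GLYPH = {"up": "▲", "down": "▼", "none": ""}
_LABEL_RANK = {"O": 0, "A": 1, "": 2}
_DIR_RANK = {"down": 0, "up": 1, "none": 2}


def table1_report(records: pd.DataFrame) -> pd.DataFrame:
    """Report of TNF-upregulated genes carrying a promoter κB motif and
    HS-induced HSF1 binding: HS-direction glyph, HS_TNF/TNF ratio and the
    combined-effect label, ordered antagonistic (O) block, co-activated (A)
    block, then unlabelled rows."""
    sel = records[
        (records["call_tnf"] == "up") & records["kb_motif"] & records["hsf1_induced"]
    ].copy()
    sel["hs_glyph"] = [_HS_GLYPH[c] for c in sel["call_hs"]]
    sel["_rank"] = [
        (_LABEL_RANK[l], _DIR_RANK[d]) for l, d in zip(sel["table_label"], sel["call_hs"])
    ]
    sel = sel.sort_index(kind="mergesort").sort_values("_rank", kind="mergesort")
    out = sel[["hs_glyph", "ratio_hstnf_vs_tnf", "table_label"]].copy()
    out.columns = ["hs_modulation", "ratio_hstnf_vs_tnf", "combined_effect"]
    return out


def load_reference_table() -> pd.DataFrame:
    """The packaged worked-example set: 27 TNFα-upregulated genes with promoter
    κB motifs and HS-induced HSF1 binding, their direction of response to heat
    shock alone, their HS_TNF/TNF expression ratio, and the published combined-
    effect label."""
    path = resources.files("tfcrosstalk.data").joinpath("tnf_up_kb_hsf1_reference.tsv")
    with path.open() as fh:
        ref = pd.read_csv(fh, sep="\t", keep_default_na=False)
    ref["label"] = ref["label"].fillna("")
    return ref


def classify_reference_table(thresholds=DEFAULT_THRESHOLDS, assumed_q: float = 0.01) -> pd.DataFrame:
    """Run the combined-effect classifier over the packaged reference set.

    The reference prints ratios but no q-values; ``assumed_q`` treats every
    printed ratio as significant, so the check is on the deterministic part of
    the rule (direction and thresholds).
    """
    ref = load_reference_table().copy()
    modes, labels = [], []
    for rec in ref.itertuples(index=False):
        mode = classify_mode("up", float(rec.ratio_hstnf_vs_tnf), assumed_q, thresholds)
        modes.append(mode)
        labels.append(table_label(mode, rec.hs_direction))
    ref["predicted_mode"] = modes
    ref["predicted_label"] = labels
    return ref
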