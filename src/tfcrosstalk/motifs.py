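"""PWM models and promoter scanning for κB and HSE motifs.

Proximal promoters (the 1000 bp upstream of the TSS) are scanned on both
strands with log-odds position weight matrices.  A window is a hit when its
score reaches ``rel_threshold`` times the maximum attainable score of the
matrix (a TRANSFAC-style relative-score convention).

Two default matrices ship with the package: the canonical 10-bp NF-κB
(RelA/p50) decamer GGGRNNYYCC, read from a JASPAR-style data file, and a
heat-shock element built by :func:`build_hse_pwm` as ≥3 alternating-orientation
nGAAn pentamer units (consensus for three units: nGAAnnTTCnnGAAn).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

from .errors import ConfigurationError, InputError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)
DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_REL_THRESHOLD = 0.8


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Probability matrix over A/C/G/T columns with a background model.

    ``matrix`` has shape (4, width) in A, C, G, T row order; a pseudocount is
    added to every cell and columns renormalised at construction, so columns
    always sum to one.
    """

    name: str
    matrix: np.ndarray
    background: Sequence[float] = UNIFORM_BACKGROUND
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != 4:
            raise ConfigurationError("PWM matrix must have shape (4, width)")
        if m.shape[1] < 4:
            raise ConfigurationError("PWM width must be >= 4")
        if np.any(m < 0):
            raise ConfigurationError("PWM entries must be non-negative")
        m = m + self.pseudocount
        self.matrix = m / m.sum(axis=0, keepdims=True)
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
            raise ConfigurationError("background must be 4 probabilities summing to 1")
        self.background = bg

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """log2(p / background) per cell, in bits."""
        return np.log2(self.matrix / self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))

    def score(self, window: str) -> float:
        """Log-odds score of one window of length ``width`` (forward strand)."""
        if len(window) != self.width:
            raise InputError("window length must equal PWM width")
        lo = self.log_odds
        total = 0.0
        for j, base in enumerate(window.upper()):
            if base not in _BASE_INDEX:
                return float("-inf")
            total += lo[_BASE_INDEX[base], j]
        return float(total)


# --------------------------------------------------------------------------
# Default matrices
# --------------------------------------------------------------------------

def kb_pwm() -> PWM:
    """Canonical NF-κB decamer (GGGRNNYYCC), from the packaged data file."""
    with resources.files("tfcrosstalk.data").joinpath("kb_canonical.jaspar").open() as fh:
        return read_jaspar(fh)[0]


def build_hse_pwm(n_units: int = 3, match_prob: float = 0.94, name: str | None = None) -> PWM:
    """Heat-shock element PWM of ``n_units`` alternating nGAAn pentamers.

    Odd-numbered units are reversed in orientation (nTTCn), so the three-unit
    consensus is nGAAnnTTCnnGAAn.  Invariant positions carry ``match_prob`` on
    the consensus base; ``n`` positions sit at the uniform background.
    """
    if n_units < 3:
        raise ConfigurationError("an HSE needs >= 3 nGAAn units")
    if not 0.25 < match_prob < 1:
        raise ConfigurationError("match_prob must lie in (0.25, 1)")
    cols = []
    off = (1.0 - match_prob) / 3.0
    for unit in range(n_units):
        core = "GAA" if unit % 2 == 0 else "TTC"
        for pos, letter in enumerate("N" + core + "N"):
            if letter == "N":
                cols.append(np.full(4, 0.25))
            else:
                col = np.full(4, off)
                col[_BASE_INDEX[letter]] = match_prob
                cols.append(col)
    matrix = np.column_stack(cols)
    return PWM(name or f"HSE_{n_units}x_nGAAn", matrix, pseudocount=0.0)


# --------------------------------------------------------------------------
# JASPAR-style I/O (parsing through Biopython)
# --------------------------------------------------------------------------

def read_jaspar(handle_or_path) -> list[PWM]:
    """Read PWMs from JASPAR-style plain text (counts or probabilities)."""
    if hasattr(handle_or_path, "read"):
        records = bio_motifs.parse(handle_or_path, "jaspar")
    else:
        with open(handle_or_path) as fh:
            records = bio_motifs.parse(fh, "jaspar")
    out = []
    for rec in records:
        counts = np.array([list(rec.counts[b]) for b in BASES], dtype=float)
        name = rec.name or rec.matrix_id or "motif"
        # probability matrices (columns already normalised) are taken as-is;
        # raw count matrices get the default pseudocount before normalisation
        is_probs = np.allclose(counts.sum(axis=0), 1.0, atol=1e-3)
        out.append(PWM(str(name), counts, pseudocount=0.0 if is_probs else DEFAULT_PSEUDOCOUNT))
    if not out:
        raise InputError("no motifs found in JASPAR input")
    return out


def write_jaspar(pwms: Iterable[PWM], path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name} {pwm.name}\n")
            for i, base in enumerate(BASES):
                row = " ".join(f"{v:.6f}" for v in pwm.matrix[i])
                fh.write(f"{base} [ {row} ]\n")


# --------------------------------------------------------------------------
# Scanning
# --------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    """A/C/G/T → 0..3, anything else (N) → 4."""
    table = np.full(256, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        table[ord(base)] = idx
        table[ord(base.lower())] = idx
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _scan_one_strand(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Window scores along one strand; windows containing N score −inf."""
    w = log_odds.shape[1]
    n_windows = codes.size - w + 1
    if n_windows <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    padded = np.vstack([log_odds, np.full((1, w), -np.inf)])
    scores = padded[windows, np.arange(w)].sum(axis=1)
    return scores


def scan_pwm(sequence: str, pwm: PWM, rel_threshold: float = DEFAULT_REL_THRESHOLD) -> pd.DataFrame:
    """Scan both strands; report windows scoring ≥ rel_threshold × max score.

    Offsets are 0-based positions of the window start on the forward
    sequence regardless of strand.  Sequences shorter than the matrix give an
    empty result.
    """
    if not 0 < rel_threshold <= 1:
        raise ConfigurationError("rel_threshold must lie in (0, 1]")
    cutoff = rel_threshold * pwm.max_score
    codes = _encode(sequence)
    w = pwm.width
    lo = pwm.log_odds
    rows = []
    fwd = _scan_one_strand(codes, lo)
    for off in np.flatnonzero(fwd >= cutoff):
        rows.append((int(off), "+", float(fwd[off])))
    rc_codes = _encode(reverse_complement(sequence))
    rev = _scan_one_strand(rc_codes, lo)
    L = len(sequence)
    for off_rc in np.flatnonzero(rev >= cutoff):
        rows.append((L - w - int(off_rc), "-", float(rev[off_rc])))
    hits = pd.DataFrame(rows, columns=["offset", "strand", "score"])
    return hits.sort_values(["offset", "strand"], kind="mergesort").reset_index(drop=True)


def read_promoters(fasta_path) -> dict:
    """Promoter records keyed by gene id; duplicate ids are an input error."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise InputError(f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def motif_presence(
    promoters: Mapping[str, str] | str,
    pwms: Iterable[PWM],
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
    return_hits: bool = False,
):
    """Per-gene boolean flag per motif: ≥1 hit anywhere in the promoter.

    ``promoters`` is a gene→sequence mapping or a FASTA path.  With
    ``return_hits`` the per-window hit table (gene, motif, offset, strand,
    score) is returned alongside the flag table.
    """
    if not isinstance(promoters, Mapping):
        promoters = read_promoters(promoters)
    pwms = list(pwms)
    flags = pd.DataFrame(
        False, index=sorted(promoters), columns=[p.name for p in pwms], dtype=bool
    )
    flags.index.name = "gene_id"
    all_hits = []
    for gene in flags.index:
        seq = promoters[gene]
        for pwm in pwms:
            hits = scan_pwm(seq, pwm, rel_threshold)
            if not hits.empty:
                flags.loc[gene, pwm.name] = True
                if return_hits:
                    h = hits.copy()
                    h.insert(0, "motif", pwm.name)
                    h.insert(0, "gene_id", gene)
                    all_hits.append(h)
    if return_hits:
        hit_table = (
            pd.concat(all_hits, ignore_index=True)
            if all_hits
            else pd.DataFrame(columns=["gene_id", "motif", "offset", "strand", "score"])
        )
        return flags, hit_table
    return flags
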