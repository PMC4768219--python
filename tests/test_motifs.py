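"""PWM construction and scanning, checked against exhaustive enumeration."""

import numpy as np
import pandas as pd
import pytest

from tfcrosstalk.errors import ConfigurationError, InputError
from tfcrosstalk.motifs import (
    PWM,
    build_hse_pwm,
    kb_pwm,
    motif_presence,
    read_jaspar,
    reverse_complement,
    scan_pwm,
    write_jaspar,
)

BASES = "ACGT"


def brute_force_scan(seq, pwm, rel_threshold):
    """Independent oracle: score every window on both strands directly."""
    seq = seq.upper()
    cutoff = rel_threshold * pwm.max_score
    hits = []
    w = pwm.width
    for off in range(len(seq) - w + 1):
        fwd = pwm.score(seq[off : off + w])
        if fwd >= cutoff:
            hits.append((off, "+", fwd))
        rev = pwm.score(reverse_complement(seq[off : off + w]))
        if rev >= cutoff:
            hits.append((off, "-", rev))
    return sorted(hits)


def random_pwm(rng, width):
    return PWM(f"toy{width}", rng.dirichlet(np.ones(4), size=width).T, pseudocount=0.0)


# ------------------------------------------------------------- construction
def test_hse_width_is_five_per_unit():
    assert build_hse_pwm(3).width == 15
    assert build_hse_pwm(5).width == 25


def test_hse_needs_three_units():
    with pytest.raises(ConfigurationError):
        build_hse_pwm(2)


def test_hse_consensus_is_alternating_pentamers():
    pwm = build_hse_pwm(3)
    consensus = pwm.consensus
    assert consensus[1:4] == "GAA" and consensus[6:9] == "TTC" and consensus[11:14] == "GAA"


def test_pwm_columns_sum_to_one():
    for pwm in (kb_pwm(), build_hse_pwm(4)):
        np.testing.assert_allclose(pwm.matrix.sum(axis=0), 1.0, atol=1e-9)


def test_pwm_width_minimum():
    with pytest.raises(ConfigurationError):
        PWM("tiny", np.full((4, 3), 0.25))


def test_jaspar_roundtrip(tmp_path):
    pwms = [kb_pwm(), build_hse_pwm(3)]
    path = tmp_path / "m.jaspar"
    write_jaspar(pwms, path)
    back = read_jaspar(path)
    assert [p.name for p in back] == [p.name for p in pwms]
    np.testing.assert_allclose(back[0].matrix, pwms[0].matrix, atol=1e-3)


# ------------------------------------------------------------------ scoring
def test_consensus_scores_pwm_maximum():
    for pwm in (kb_pwm(), build_hse_pwm(3)):
        assert pwm.score(pwm.consensus) == pytest.approx(pwm.max_score)


def test_reverse_complement_of_consensus_reaches_same_best_score():
    pwm = build_hse_pwm(3)
    fwd = scan_pwm(pwm.consensus, pwm, 0.5)
    rev = scan_pwm(reverse_complement(pwm.consensus), pwm, 0.5)
    assert fwd["score"].max() == pytest.approx(rev["score"].max())


def test_scores_mirror_on_reverse_complement_with_strand_swap():
    rng = np.random.default_rng(4)
    pwm = build_hse_pwm(3)
    flank = lambda n: "".join(rng.choice(list(BASES), n))
    seq = flank(20) + pwm.consensus + flank(10) + reverse_complement(pwm.consensus) + flank(15)
    a = scan_pwm(seq, pwm, 0.8)
    b = scan_pwm(reverse_complement(seq), pwm, 0.8)
    assert not a.empty
    assert sorted(a["score"].astype(float).round(9)) == sorted(b["score"].astype(float).round(9))
    # strands swap: the forward hits of one are the reverse hits of the other
    assert sorted(a["strand"]) == sorted(b["strand"].map({"+": "-", "-": "+"}))


def test_empty_and_short_sequences_give_no_hits():
    pwm = build_hse_pwm(3)
    assert scan_pwm("", pwm, 0.8).empty
    assert scan_pwm("GAAT", pwm, 0.8).empty


def test_windows_containing_n_are_skipped():
    pwm = build_hse_pwm(3)
    seq = pwm.consensus.replace("GAA", "GNA", 1)
    hits = scan_pwm(seq, pwm, 0.99)
    assert hits.empty


@pytest.mark.parametrize("seed", range(8))
def test_scan_equals_brute_force_enumeration(seed):
    rng = np.random.default_rng(seed)
    width = int(rng.integers(4, 7))
    pwm = random_pwm(rng, width)
    seq = "".join(rng.choice(list(BASES + "N"), size=int(rng.integers(width, 50)),
                             p=[0.24, 0.24, 0.24, 0.24, 0.04]))
    got = [
        (int(r.offset), r.strand, pytest.approx(r.score, abs=1e-9))
        for r in scan_pwm(seq, pwm, 0.5).itertuples(index=False)
    ]
    expected = [(o, s, pytest.approx(v, abs=1e-9)) for o, s, v in brute_force_scan(seq, pwm, 0.5)]
    assert got == expected


def test_raising_threshold_never_adds_hits():
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list(BASES), 500))
    pwm = kb_pwm()
    loose = scan_pwm(seq, pwm, 0.6)
    tight = scan_pwm(seq, pwm, 0.8)
    loose_set = set(zip(loose["offset"], loose["strand"]))
    tight_set = set(zip(tight["offset"], tight["strand"]))
    assert tight_set <= loose_set


# ----------------------------------------------------------------- presence
def test_presence_flags_planted_genes(small_study):
    truth = small_study.truth.genes
    flags = motif_presence(small_study.promoters, [small_study.pwms["kb"]], 0.8)
    planted = truth.loc[truth["kb_planted"], "gene_id"]
    assert flags.loc[planted, "kb_canonical"].all()


def test_presence_invariant_to_record_order(small_study):
    pwms = [small_study.pwms["kb"]]
    fwd = motif_presence(small_study.promoters, pwms, 0.8)
    rev = motif_presence(dict(reversed(list(small_study.promoters.items()))), pwms, 0.8)
    pd.testing.assert_frame_equal(fwd, rev)


def test_duplicate_fasta_ids_rejected(tmp_path):
    fasta = tmp_path / "dup.fasta"
    fasta.write_text(">g1\nACGTACGT\n>g1\nACGTACGT\n")
    with pytest.raises(InputError):
        motif_presence(str(fasta), [build_hse_pwm(3)], 0.8)


def test_background_hit_rate_matches_unplanted_estimate():
    """With plant probability zero, the per-gene flag rate equals the false-
    positive rate estimated on an independent unplanted background."""
    rng = np.random.default_rng(10)
    pwm = kb_pwm()
    make = lambda n, L: {f"g{i}": "".join(rng.choice(list(BASES), L)) for i in range(n)}
    a = motif_presence(make(300, 1000), [pwm], 0.8)["kb_canonical"].mean()
    b = motif_presence(make(300, 1000), [pwm], 0.8)["kb_canonical"].mean()
    assert abs(a - b) < 0.12
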