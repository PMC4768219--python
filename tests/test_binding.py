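"""Regulatory windows, peak assignment, the Poisson caller and induction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tfcrosstalk.binding import (
    assign_peaks,
    call_induced_binding,
    call_peaks_simple,
    make_window,
    windows_table,
)
from tfcrosstalk.errors import ConfigurationError, DegenerateDataError, InputError


# ----------------------------------------------------------------- windows
@pytest.mark.parametrize(
    "tss,strand,expected",
    [
        (10000, "+", (2500, 12500)),
        (10000, "-", (7500, 17500)),
        (3000, "+", (0, 5500)),  # clipped at the chromosome start
    ],
)
def test_make_window_examples(tss, strand, expected):
    win = make_window("chr1", tss, strand)
    assert (win.start, win.end) == expected


def test_make_window_rejects_unknown_strand():
    with pytest.raises(InputError):
        make_window("chr1", 100, ".")


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.integers(10000, 10**7))
def test_window_strand_mirror_symmetry(tss):
    """Reflecting the coordinate axis and flipping strand reflects the window."""
    L = 2 * 10**7
    plus = make_window("c", tss, "+")
    minus = make_window("c", L - tss, "-")
    assert (plus.start, plus.end) == (L - minus.end, L - minus.start)


def test_windows_table_single_5prime_tss_per_gene():
    ann = pd.DataFrame(
        {
            "gene_id": ["g1", "g1", "g2", "g2"],
            "chrom": "c",
            "tss": [50000, 40000, 80000, 90000],
            "strand": ["+", "+", "-", "-"],
        }
    )
    wins = windows_table(ann)
    assert len(wins) == 2
    # '+': 5'-most is the smaller TSS; '-': the larger
    assert wins.set_index("gene_id").loc["g1", "start"] == 40000 - 7500
    assert wins.set_index("gene_id").loc["g2", "end"] == 90000 + 7500


# -------------------------------------------------------------- assignment
def _win_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def test_assignment_half_open_boundaries():
    windows = _win_frame([("g", "c", 2500, 12500, "+")])
    inside = pd.DataFrame({"chrom": ["c"], "start": [12499], "end": [12600], "name": ["p"], "score": [1.0], "strand": ["."]})
    outside = pd.DataFrame({"chrom": ["c"], "start": [12500], "end": [12600], "name": ["p"], "score": [1.0], "strand": ["."]})
    assert len(assign_peaks(inside, windows)) == 1
    assert len(assign_peaks(outside, windows)) == 0


def test_assignment_matches_quadratic_oracle():
    rng = np.random.default_rng(6)
    windows = _win_frame(
        [(f"g{i}", "c", s, s + rng.integers(500, 5000), "+")
         for i, s in enumerate(rng.integers(0, 50000, size=30))]
    )
    peaks = pd.DataFrame(
        {
            "chrom": "c",
            "start": rng.integers(0, 52000, size=60),
        }
    )
    peaks["end"] = peaks["start"] + rng.integers(100, 900, size=60)
    peaks["name"] = [f"p{i}" for i in range(60)]
    peaks["score"] = rng.uniform(1, 10, size=60)
    peaks["strand"] = "."
    got = set(zip(*[assign_peaks(peaks, windows)[c] for c in ("gene_id", "peak_index")]))
    expected = {
        (w.gene_id, i)
        for i, p in enumerate(peaks.itertuples(index=False))
        for w in windows.itertuples(index=False)
        if p.start < w.end and w.start < p.end
    }
    assert got == expected


def test_assignment_order_invariant_and_dedup_idempotent():
    rng = np.random.default_rng(7)
    windows = _win_frame([("g1", "c", 0, 10000, "+"), ("g2", "c", 8000, 20000, "+")])
    peaks = pd.DataFrame(
        {"chrom": "c", "start": [500, 9000, 15000], "end": [900, 9400, 15600],
         "name": list("abc"), "score": [1.0, 2.0, 3.0], "strand": "."}
    )
    base = assign_peaks(peaks, windows)
    shuffled = assign_peaks(peaks.sample(frac=1, random_state=1).reset_index(drop=True), windows)
    assert set(zip(base["gene_id"], base["start"])) == set(zip(shuffled["gene_id"], shuffled["start"]))
    doubled = assign_peaks(pd.concat([peaks, peaks], ignore_index=True).drop_duplicates(), windows)
    assert set(zip(doubled["gene_id"], doubled["start"])) == set(zip(base["gene_id"], base["start"]))


def test_chrom_mismatch_yields_zero_overlap():
    windows = _win_frame([("g", "cA", 0, 1000, "+")])
    peaks = pd.DataFrame({"chrom": ["cB"], "start": [10], "end": [200], "name": ["p"], "score": [1.0], "strand": ["."]})
    assert assign_peaks(peaks, windows).empty


# ------------------------------------------------------------- peak caller
def _track(counts, bin_width=100):
    return pd.DataFrame({"chrom": "c", "start": np.arange(len(counts)) * bin_width, "count": counts})


def test_identical_track_and_reference_give_no_peaks():
    rng = np.random.default_rng(0)
    counts = rng.poisson(10, size=500)
    assert call_peaks_simple(_track(counts), _track(counts)).empty


def test_poisson_tail_closed_form():
    # a single hot bin: p-value must equal the exact Poisson tail sum
    ref = _track(np.full(200, 5))
    obs = np.full(200, 5)
    obs[37] = 15
    peaks = call_peaks_simple(_track(obs), ref, fdr=0.5)
    lam = 5 * obs.sum() / ref["count"].sum()
    from math import exp, factorial

    tail = sum(exp(-lam) * lam**k / factorial(k) for k in range(15, 60))
    # the peak score is -log10 of the BH-adjusted p of that one bin (=p*m/1)
    assert not peaks.empty
    expected = -np.log10(min(1.0, tail * 200))
    assert peaks["score"].max() == pytest.approx(expected, rel=1e-6)


def test_null_false_positive_bin_fraction_below_fdr():
    rates = []
    for seed in range(50):
        rng = np.random.default_rng(seed)
        obs = _track(rng.poisson(10, size=400))
        ref = _track(rng.poisson(10, size=400))
        peaks = call_peaks_simple(obs, ref, fdr=0.05)
        sig_bins = int(sum((p.end - p.start) // 100 for p in peaks.itertuples(index=False)))
        rates.append(sig_bins / 400)
    assert np.mean(rates) <= 0.05


def test_zero_depth_reference_is_degenerate():
    with pytest.raises(DegenerateDataError):
        call_peaks_simple(_track(np.ones(10, dtype=int)), _track(np.zeros(10, dtype=int)))


# ---------------------------------------------------------------- induction
def test_planted_induced_genes_recovered(small_study):
    windows = windows_table(small_study.annotation)
    calls = call_induced_binding(small_study.peaks, windows)
    truth = small_study.truth.genes.set_index("gene_id")
    merged = calls.set_index("gene_id").join(truth["binding_induced"])
    sens = merged.loc[merged["binding_induced"], "induced_any"].mean()
    assert sens >= 0.95


def test_identical_peak_sets_give_no_induction(small_study):
    windows = windows_table(small_study.annotation)
    same = small_study.peaks["Ctr"]
    calls = call_induced_binding({"Ctr": same, "HS_10": same, "HS_20": same}, windows)
    assert not calls["induced_any"].any()


def test_missing_condition_is_configuration_error(small_study):
    windows = windows_table(small_study.annotation)
    with pytest.raises(ConfigurationError):
        call_induced_binding({"Ctr": small_study.peaks["Ctr"]}, windows)


def test_induced_any_is_union_of_timepoints(small_study):
    windows = windows_table(small_study.annotation)
    calls = call_induced_binding(small_study.peaks, windows)
    assert (calls["induced_any"] == (calls["induced_hs10"] | calls["induced_hs20"])).all()


def test_track_route_calls_induction_from_window_counts(small_study):
    """With binned tag tracks supplied, induction comes from the depth-scaled
    Poisson window-count test rather than peak-score ratios."""
    from tfcrosstalk.simulate import simulate_tag_tracks

    tracks = simulate_tag_tracks(small_study.config, small_study.peaks)
    windows = windows_table(small_study.annotation)
    calls = call_induced_binding(
        small_study.peaks,
        windows,
        tracks_by_condition={k: v for k, v in tracks.items() if k != "input"},
    )
    truth = small_study.truth.genes.set_index("gene_id")
    merged = calls.set_index("gene_id").join(truth["binding_induced"])
    assert merged.loc[merged["binding_induced"], "induced_any"].mean() >= 0.9
    assert merged.loc[~merged["binding_induced"], "induced_any"].mean() <= 0.1


def test_simulated_tracks_are_enriched_over_input_at_peaks(small_study):
    from tfcrosstalk.simulate import simulate_tag_tracks

    tracks = simulate_tag_tracks(small_study.config, small_study.peaks)
    peaks = call_peaks_simple(tracks["HS_10"], tracks["input"], fdr=0.05)
    assert not peaks.empty
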