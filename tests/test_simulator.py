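"""Simulator: truncation rules, insertion splicing, read generation."""

from __future__ import annotations

import numpy as np
import pytest

from tdnaseeker.formats import ReferenceSequence, reverse_complement
from tdnaseeker.simulate import (
    MIN_RETAINED,
    PlacementError,
    ReadSimParams,
    TDNAConstruct,
    expected_pair_count,
    insert_tdna,
    random_genome,
    random_tdna,
    simulate_reads,
    truncate_tdna,
)


class ForcedRng:
    """Stand-in rng whose float draws are scripted (for deterministic paths)."""

    def __init__(self, randoms):
        self._randoms = list(randoms)

    def random(self, *args, **kwargs):
        return self._randoms.pop(0)

    def integers(self, *args, **kwargs):  # pragma: no cover - not used when full
        raise AssertionError("unexpected integer draw")


@pytest.fixture(scope="module")
def construct():
    return random_tdna(np.random.default_rng(7), 6743)


def test_truncate_full_outcome_returns_whole_construct(construct):
    seq, st, end, truncated = truncate_tdna(construct, ForcedRng([0.4]))
    assert (st, end, truncated) == (1, 6743, False)
    assert seq == construct.sequence


def test_truncate_outcomes_respect_minimum_length(construct, rng):
    saw_truncated = False
    for _ in range(500):
        seq, st, end, truncated = truncate_tdna(construct, rng)
        assert 1 <= st <= end <= construct.length
        assert end - st + 1 >= MIN_RETAINED
        assert seq == construct.sequence[st - 1 : end]
        if truncated:
            saw_truncated = True
            assert (st, end) != (1, construct.length)
        else:
            assert (st, end) == (1, construct.length)
    assert saw_truncated


def test_truncate_fraction_is_about_half(construct):
    rng = np.random.default_rng(123)
    n_truncated = sum(truncate_tdna(construct, rng)[3] for _ in range(10_000))
    assert 0.45 <= n_truncated / 10_000 <= 0.55


def test_truncate_rejects_short_construct():
    with pytest.raises(ValueError):
        TDNAConstruct("tiny", "ACGT" * 10)  # 40 bp < minimum


def test_insert_forced_position_splice_arithmetic(rng):
    genome = random_genome(10_000, rng)
    construct = random_tdna(rng, 600)
    # scripted draws: full construct (0.4 < 0.5), forward orientation (0.6)
    mutated, truth = insert_tdna(
        genome, construct, 1, ForcedRng([0.4, 0.6]), positions=[("chr1", 5000)]
    )
    assert len(mutated[0]) == 10_000 + 600
    t = truth[0]
    assert (t.chr, t.position, t.tdna_st, t.tdna_end) == ("chr1", 5000, 1, 600)
    assert (t.orientation, t.truncated) == ("forward", False)
    assert mutated[0].sequence[5000:5600] == construct.sequence
    assert mutated[0].sequence[:5000] == genome[0].sequence[:5000]
    assert mutated[0].sequence[5600:] == genome[0].sequence[5000:]


def test_insert_zero_insertions_is_identity(rng):
    genome = random_genome(5000, rng)
    mutated, truth = insert_tdna(genome, random_tdna(rng, 100), 0, rng)
    assert truth == []
    assert mutated == genome


def test_insert_respects_spacing_and_truth_invariants():
    for seed in (1, 2, 3):
        rng = np.random.default_rng(seed)
        genome = random_genome(2_000_000, rng)
        construct = random_tdna(rng)
        _, truth = insert_tdna(genome, construct, 100, rng, min_gap=2000)
        assert len(truth) == 100
        positions = sorted(t.position for t in truth)
        assert min(np.diff(positions)) >= 2000
        assert positions[0] >= 2000
        assert positions[-1] <= len(genome[0]) - 2000
        for t in truth:
            assert 1 <= t.tdna_st <= t.tdna_end <= construct.length
            assert t.tdna_end - t.tdna_st + 1 >= MIN_RETAINED
            assert t.truncated == (t.tdna_st > 1 or t.tdna_end < construct.length)


def test_insert_splice_consistency(rng):
    """The mutated genome reproduces each planted segment exactly."""
    genome = random_genome(500_000, rng)
    construct = random_tdna(rng, 1000)
    mutated, truth = insert_tdna(genome, construct, 20, rng, min_gap=5000)
    offset = 0
    for t in truth:  # truths are sorted by position
        segment = construct.sequence[t.tdna_st - 1 : t.tdna_end]
        if t.orientation == "reverse":
            segment = reverse_complement(segment)
        start = t.position + offset
        assert mutated[0].sequence[start : start + len(segment)] == segment
        offset += len(segment)


def test_insert_impossible_spacing_reports_progress(rng):
    genome = random_genome(30_000, rng)
    with pytest.raises(PlacementError, match="/20"):
        insert_tdna(genome, random_tdna(rng, 100), 20, rng, min_gap=2000,
                    max_tries_per_insertion=50)


def test_read_count_follows_coverage_formula(tmp_path, rng):
    genome = random_genome(10_000, rng)
    params = ReadSimParams(coverage=5, read_length=150, seed=1)
    n = simulate_reads(genome, params, tmp_path / "r1.fq", tmp_path / "r2.fq")
    assert n == expected_pair_count(10_000, 5, 150) == 167
    assert abs(n - 166) <= 17  # within 10% of coverage * G / (2 * rl)
    n_records = (tmp_path / "r1.fq").read_text().count("@sim_")
    assert n_records == n


@pytest.mark.parametrize(
    "length, coverage, rl", [(10_000, 5, 150), (7777, 3.3, 100), (50_000, 0.5, 36)]
)
def test_read_count_formula_arbitrary_parameters(tmp_path, rng, length, coverage, rl):
    genome = random_genome(length, rng)
    params = ReadSimParams(coverage=coverage, read_length=rl,
                           fragment_mean=3 * rl, fragment_sd=10, seed=2)
    n = simulate_reads(genome, params, tmp_path / "a1.fq", tmp_path / "a2.fq")
    assert abs(n - coverage * length / (2 * rl)) <= 1


def test_noiseless_reads_are_exact_substrings(tmp_path, rng):
    genome = random_genome(10_000, rng)
    params = ReadSimParams(coverage=2, base_error_rate=0.0, seed=3)
    simulate_reads(genome, params, tmp_path / "n1.fq", tmp_path / "n2.fq")
    seq = genome[0].sequence
    rc = reverse_complement(seq)
    for fq in ("n1.fq", "n2.fq"):
        lines = (tmp_path / fq).read_text().splitlines()
        for read in lines[1::4]:
            assert read in seq or read in rc


def test_same_seed_gives_byte_identical_fastq(tmp_path, rng):
    genome = random_genome(20_000, rng)
    params = ReadSimParams(coverage=3, seed=99)
    simulate_reads(genome, params, tmp_path / "x1.fq", tmp_path / "x2.fq")
    simulate_reads(genome, params, tmp_path / "y1.fq", tmp_path / "y2.fq")
    assert (tmp_path / "x1.fq").read_bytes() == (tmp_path / "y1.fq").read_bytes()
    assert (tmp_path / "x2.fq").read_bytes() == (tmp_path / "y2.fq").read_bytes()


def test_params_validation():
    with pytest.raises(ValueError):
        ReadSimParams(coverage=0)
    with pytest.raises(ValueError):
        ReadSimParams(coverage=1, read_length=20)
    with pytest.warns(UserWarning, match="fragment_mean"):
        ReadSimParams(coverage=1, read_length=150, fragment_mean=250)
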