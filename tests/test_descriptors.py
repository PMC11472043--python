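"""Context-descriptor module: windows, GC, block complexity, providers,
normalization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import guidepost as gp
from guidepost.descriptors import (BoundsError, ConfigurationError,
                                   ContextWindow, ContigLookupError,
                                   MissingTrackError, WINDOW_LENGTH,
                                   reverse_complement)

window_seq = st.text(alphabet="ACGT", min_size=WINDOW_LENGTH, max_size=WINDOW_LENGTH)


def _genome(seed=0, length=2000):
    return {"chr1": gp.simulate_genome(length, seed)}


def _pair(genome, start=500, strand="+"):
    seq = genome["chr1"][start:start + 23]
    if strand == "-":
        seq = reverse_complement(seq)
    return gp.SgRNATargetPair(seq, seq, chrom="chr1", start=start, strand=strand)


def test_window_geometry_and_centers_plus_strand():
    genome = _genome()
    pair = _pair(genome, start=500)
    windows = gp.extract_windows(genome, pair)
    assert len(windows) == 23
    for j, w in enumerate(windows):
        assert len(w.sequence) == 147
        assert w.center == 500 + j
        # window j spans [p+j-73, p+j+74) on the contig
        assert w.sequence == genome["chr1"][500 + j - 73:500 + j + 74]
        assert w.sequence[73] == pair.target_seq[j]


def test_window_centers_minus_strand_match_target_seq():
    genome = _genome(seed=1)
    pair = _pair(genome, start=700, strand="-")
    windows = gp.extract_windows(genome, pair)
    for j, w in enumerate(windows):
        assert w.center == 700 + 22 - j
        assert w.sequence[73] == pair.target_seq[j]


def test_contig_edge_windows_are_n_padded():
    genome = _genome()
    pair = _pair(genome, start=10)
    windows = gp.extract_windows(genome, pair)
    assert windows[0].sequence.startswith("N" * 63)
    assert len(windows[0].sequence) == 147


def test_window_errors():
    genome = _genome()
    with pytest.raises(ContigLookupError):
        gp.extract_windows(genome, gp.SgRNATargetPair("A" * 23, "A" * 23,
                                                      chrom="chrX", start=100))
    with pytest.raises(BoundsError):
        gp.extract_windows(genome, gp.SgRNATargetPair("A" * 23, "A" * 23,
                                                      chrom="chr1", start=1990))


def test_gc_content_basic_and_oracle():
    assert gp.gc_content(ContextWindow("c", 73, "G" * 147)) == 1.0
    assert gp.gc_content(ContextWindow("c", 73, "AC" * 73 + "A")) == pytest.approx(73 / 147)
    # N in denominator only
    assert gp.gc_content(ContextWindow("c", 73, "N" * 147)) == 0.0


@settings(deadline=None, max_examples=30, derandomize=True)
@given(window_seq)
def test_gc_reverse_complement_invariance(seq):
    w = ContextWindow("c", 73, seq)
    wrc = ContextWindow("c", 73, reverse_complement(seq))
    assert gp.gc_content(w) == pytest.approx(gp.gc_content(wrc), abs=1e-12)
    loop = sum(1 for ch in seq if ch in "GC") / len(seq)
    assert gp.gc_content(w) == pytest.approx(loop, abs=1e-12)


def test_bdm_single_and_two_block_closed_forms():
    block = "ACGTACGTACGT"
    table = {block: 5.0}
    w = ContextWindow("c", 73, (block * 13)[:147])
    # 12 full blocks of the same 12-mer; remainder dropped
    assert gp.bdm_score(w, 12, table) == pytest.approx(5.0 + math.log2(12))
    b2 = "AAAAAAAAAAAA"
    table2 = {block: 5.0, b2: 1.5}
    seq = block * 6 + b2 * 6 + "AAA"
    w2 = ContextWindow("c", 73, seq)
    assert gp.bdm_score(w2, 12, table2) == pytest.approx(
        5.0 + math.log2(6) + 1.5 + math.log2(6))


@settings(deadline=None, max_examples=20, derandomize=True)
@given(window_seq)
def test_bdm_matches_dictionary_accumulation_oracle(seq):
    w = ContextWindow("c", 73, seq)
    got = gp.bdm_score(w, block_size=12)
    # brute-force tally with the same entropy fallback
    blocks = [seq[i * 12:(i + 1) * 12] for i in range(len(seq) // 12)]
    tally = {}
    for b in blocks:
        tally[b] = tally.get(b, 0) + 1
    expected = 0.0
    for b, mult in tally.items():
        counts = np.array([b.count(ch) for ch in "ACGTN"], dtype=float)
        p = counts[counts > 0] / 12
        expected += float(-(p * np.log2(p)).sum() * 12) + math.log2(mult)
    assert got == pytest.approx(expected, rel=1e-12)


def test_bdm_requires_table_or_fallback():
    w = ContextWindow("c", 73, "A" * 147)
    with pytest.raises(ConfigurationError):
        gp.bdm_score(w, 12, block_table=None, fallback=False)


def test_track_provider_roundtrip_and_missing(tmp_path):
    values = {("chr1", 100): (0.7, 0.3), ("chr1", 101): (0.2, 0.9)}
    provider = gp.TrackNucleosomeProvider(values)
    path = tmp_path / "track.tsv"
    provider.to_file(path)
    loaded = gp.TrackNucleosomeProvider.from_file(path)
    w = ContextWindow("chr1", 100, "A" * 147)
    assert gp.nucleosome_scores(loaded, w) == (0.7, 0.3)
    with pytest.raises(MissingTrackError, match="chr1:999"):
        loaded.scores(ContextWindow("chr1", 999, "A" * 147))


def test_surrogate_provider_deterministic():
    w = ContextWindow("c", 73, gp.simulate_genome(200, 5)[:147])
    p = gp.SurrogateNucleosomeProvider()
    assert p.scores(w) == p.scores(w)
    occ, aff = p.scores(w)
    assert 0.0 <= aff <= 1.0 and 0.0 < occ < 1.0


def test_normalization_endpoints_degenerate_and_idempotence():
    stats = gp.NormalizationStats(mins=[0, 0, 1, 0], maxs=[2, 1, 1, 1])
    raw = np.zeros((4, 23))
    raw[0] = np.linspace(0, 2, 23)
    raw[1] = 0.25
    raw[2] = 1.0  # degenerate row -> zeros
    raw[3] = np.linspace(0, 1, 23)
    out = stats.apply(raw)
    assert out[0, 0] == 0.0 and out[0, -1] == 1.0
    assert np.all(out[2] == 0.0)
    # idempotence: re-normalizing a normalized row with its own min/max
    stats01 = gp.NormalizationStats(mins=[0] * 4, maxs=[1] * 4)
    again = stats01.apply(out)
    assert np.allclose(again, out)


def test_descriptor_matrix_matches_per_op_composition():
    genome = _genome(seed=7)
    pair = _pair(genome, start=400)
    config = gp.DescriptorConfig()
    raw = gp.raw_descriptor_matrix(genome, pair, config)
    windows = gp.extract_windows(genome, pair)
    provider = gp.SurrogateNucleosomeProvider()
    for j, w in enumerate(windows):
        assert raw[1, j] == pytest.approx(gp.gc_content(w), abs=1e-12)
        assert raw[0, j] == pytest.approx(gp.bdm_score(w, config.block_size), rel=1e-10)
        occ, aff = provider.scores(w)
        assert raw[2, j] == pytest.approx(occ, abs=1e-10)
        assert raw[3, j] == pytest.approx(aff, abs=1e-10)
    config.norm_stats = gp.NormalizationStats.fit([raw])
    norm = gp.descriptor_matrix(genome, pair, config)
    assert norm.matrix.shape == (4, 23)
    assert norm.matrix.min() >= 0.0 and norm.matrix.max() <= 1.0


def test_identical_sequence_different_locus_differs():
    """The module's purpose: context separates sequence-identical sites."""
    rng = np.random.default_rng(0)
    base = gp.simulate_genome(3000, 11)
    site = base[1000:1023]
    # plant the same 23-mer at a second, different-context locus
    genome_str = base[:2000] + site + base[2023:]
    genome = {"chr1": genome_str}
    p1 = gp.SgRNATargetPair(site, site, chrom="chr1", start=1000)
    p2 = gp.SgRNATargetPair(site, site, chrom="chr1", start=2000)
    config = gp.DescriptorConfig()
    r1 = gp.raw_descriptor_matrix(genome, p1, config)
    r2 = gp.raw_descriptor_matrix(genome, p2, config)
    assert gp.encode_pair(p1).matrix.tolist() == gp.encode_pair(p2).matrix.tolist()
    assert not np.allclose(r1, r2)
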