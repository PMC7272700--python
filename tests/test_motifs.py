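"""PWM scoring against an exhaustive oracle; promoter extraction; z-test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cachexnet.motifs import (
    MotifModel,
    PromoterSet,
    best_hit_score,
    cpg_fraction,
    extract_promoters,
    match_background,
    motif_ztest,
    read_jaspar,
    reverse_complement,
    score_sequences,
    write_jaspar,
)

BASES = "ACGT"


def oracle_best_hit(seq: str, motif: MotifModel) -> float:
    """Plain-Python exhaustive placement over both strands."""
    llr = motif.log_odds()
    idx = {b: i for i, b in enumerate(BASES + "N")}
    w = motif.width

    def window_score(s):
        return sum(llr[idx[b], j] for j, b in enumerate(s))

    candidates = []
    for strand_seq in (seq, reverse_complement(seq)):
        for off in range(len(strand_seq) - w + 1):
            candidates.append(window_score(strand_seq[off : off + w]))
    best = llr[:4].max(axis=0).sum()
    worst = llr[:4].min(axis=0).sum()
    return (max(candidates) - worst) / (best - worst)


@st.composite
def seq_and_motif(draw):
    length = draw(st.integers(min_value=4, max_value=12))
    w = draw(st.integers(min_value=4, max_value=length))
    seq = "".join(
        draw(st.lists(st.sampled_from("ACGTN"), min_size=length, max_size=length))
    )
    pfm = np.array(
        [
            [draw(st.integers(min_value=0, max_value=30)) for _ in range(w)]
            for _ in range(4)
        ],
        dtype=float,
    )
    pfm[draw(st.integers(0, 3))] += 1  # avoid an all-zero column
    return seq, MotifModel("M", "m", pfm)


class TestBestHitScore:
    def test_consensus_scores_one(self):
        m = MotifModel.from_consensus("GGGACTTTCC")
        assert best_hit_score("AA" + m.consensus + "TTT", m) == pytest.approx(1.0)

    def test_anticonsensus_scores_zero(self):
        # for an A-consensus motif with flat off-cells, C/G/T tie for the
        # column minimum, so CCCC and its complement GGGG both score worst
        m = MotifModel.from_consensus("AAAA")
        assert best_hit_score("CCCC", m) == pytest.approx(0.0)

    @settings(max_examples=300, deadline=None)
    @given(seq_and_motif())
    def test_matches_exhaustive_oracle(self, case):
        seq, motif = case
        assert best_hit_score(seq, motif) == pytest.approx(
            oracle_best_hit(seq, motif)
        )

    def test_reverse_complement_invariance(self, rng):
        m = MotifModel("M", "m", rng.integers(1, 40, size=(4, 7)))
        for _ in range(20):
            seq = "".join(rng.choice(list(BASES), size=30))
            assert best_hit_score(seq, m) == pytest.approx(
                best_hit_score(reverse_complement(seq), m)
            )

    def test_batch_equals_per_sequence(self, rng):
        m = MotifModel("M", "m", rng.integers(1, 40, size=(4, 9)))
        seqs = ["".join(rng.choice(list(BASES), size=50)) for _ in range(15)]
        batch = score_sequences(seqs, m)
        single = np.array([best_hit_score(s, m) for s in seqs])
        assert np.allclose(batch, single)

    def test_all_n_sequence_in_range(self):
        m = MotifModel.from_consensus("ACGTAC")
        s = best_hit_score("N" * 20, m)
        assert 0.0 <= s <= 1.0

    def test_sequence_shorter_than_motif_rejected(self):
        m = MotifModel.from_consensus("ACGTACGT")
        with pytest.raises(ValueError, match="shorter"):
            best_hit_score("ACG", m)


class TestMotifModel:
    def test_width_floor(self):
        with pytest.raises(ValueError, match="width"):
            MotifModel("M", "m", np.ones((4, 3)))

    def test_jaspar_roundtrip(self, tmp_path, rng):
        motifs = [
            MotifModel("MA0001", "alpha", rng.integers(0, 50, size=(4, 6)) + 1.0),
            MotifModel("MA0002", "beta", rng.integers(0, 50, size=(4, 11)) + 1.0),
        ]
        path = tmp_path / "lib.jaspar"
        write_jaspar(motifs, path)
        back = read_jaspar(path)
        assert [m.motif_id for m in back] == ["MA0001", "MA0002"]
        for a, b in zip(motifs, back):
            assert np.allclose(a.pfm, b.pfm)


class TestCpG:
    def test_cgcg_fraction(self):
        assert cpg_fraction("CGCG") == pytest.approx(2 / 3)

    def test_no_cpg(self):
        assert cpg_fraction("AATT") == 0.0


class TestExtractPromoters:
    def _genome(self, rng, n=4000):
        return {"chr1": "".join(rng.choice(list(BASES), size=n))}

    def test_plus_strand_window_coordinates(self, rng):
        genome = self._genome(rng)
        bed = pd.DataFrame(
            [{"chrom": "chr1", "start": 1000, "end": 1001,
              "name": "g1", "score": 0, "strand": "+"}]
        )
        ps = extract_promoters(bed, genome)
        assert ps.sequences["g1"] == genome["chr1"][700:1050]

    def test_minus_strand_reverse_complement(self, rng):
        genome = self._genome(rng)
        bed = pd.DataFrame(
            [{"chrom": "chr1", "start": 1000, "end": 1001,
              "name": "g1", "score": 0, "strand": "-"}]
        )
        ps = extract_promoters(bed, genome)
        assert ps.sequences["g1"] == reverse_complement(genome["chr1"][950:1300])

    def test_contig_edge_padded_and_flagged(self, rng):
        genome = self._genome(rng, n=500)
        bed = pd.DataFrame(
            [{"chrom": "chr1", "start": 100, "end": 101,
              "name": "edge", "score": 0, "strand": "+"}]
        )
        ps = extract_promoters(bed, genome)
        assert ps.sequences["edge"].startswith("N" * 200)
        assert "edge" in ps.flagged
        assert len(ps.sequences["edge"]) == 350


def _random_promoters(rng, n, length=120, prefix="p"):
    return {
        f"{prefix}{i}": "".join(rng.choice(list(BASES), size=length))
        for i in range(n)
    }


class TestZtestAndBackground:
    def test_foreground_equal_background_is_null(self, rng):
        seqs = _random_promoters(rng, 20)
        ps = PromoterSet(seqs, (-300, 50))
        m = MotifModel.from_consensus("GGGACTTTCC")
        res = motif_ztest(ps, ps, m)
        assert res.z == pytest.approx(0.0)
        assert res.p_value == pytest.approx(0.5)

    def test_planted_motif_detected(self, rng):
        m = MotifModel.from_consensus("GGGACTTTCC")
        fg = {}
        for i in range(25):
            s = list("".join(rng.choice(list(BASES), size=120)))
            pos = rng.integers(0, 110)
            s[pos : pos + 10] = m.consensus
            fg[f"f{i}"] = "".join(s)
        bg = _random_promoters(rng, 30, prefix="b")
        res = motif_ztest(PromoterSet(fg, (-300, 50)), PromoterSet(bg, (-300, 50)), m)
        assert res.p_value < 0.01
        assert res.fg_fraction > res.bg_fraction

    def test_background_smaller_than_foreground_rejected(self, rng):
        fg = PromoterSet(_random_promoters(rng, 5))
        bg = PromoterSet(_random_promoters(rng, 3, prefix="b"))
        with pytest.raises(ValueError, match="at least as large"):
            motif_ztest(fg, bg, MotifModel.from_consensus("ACGTT"))

    def test_match_pool_equals_fg_returns_permutation(self, rng):
        fg = PromoterSet(_random_promoters(rng, 12))
        bg = match_background(fg, fg, tolerance=1.0, rng=rng)
        assert set(bg.sequences.values()) == set(fg.sequences.values())

    def test_matched_background_cpg_close(self, rng):
        fg = PromoterSet(_random_promoters(rng, 15))
        pool = PromoterSet(_random_promoters(rng, 150, prefix="q"))
        bg = match_background(fg, pool, tolerance=0.02, rng=rng)
        diff = abs(fg.cpg_fractions().mean() - bg.cpg_fractions().mean())
        assert diff <= 0.02
        assert len(bg) == len(fg)

    def test_exhausted_pool_raises(self, rng):
        fg = PromoterSet({"a": "CG" * 60})  # extreme CpG content
        pool = PromoterSet({"x": "AT" * 60})
        with pytest.raises(ValueError, match="exhausted"):
            match_background(fg, pool, tolerance=0.01, rng=rng)
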