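"""PWM promoter-motif over-representation (Pscan-style).

Promoters are scored with the best log-odds hit of a position weight
matrix over both strands, min-max rescaled to [0, 1] by the matrix's
worst and best attainable scores; enrichment of a foreground promoter set
(e.g. promoters of up-regulated genes, -300..+50 around the TSS) against
a CpG-matched background is tested with a one-sided z statistic on the
mean best-hit score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_BASE_INDEX["N"] = 4
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

UNIFORM_BG = np.full(4, 0.25)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def cpg_fraction(seq: str) -> float:
    """Fraction of dinucleotide positions that are CG (CpG density)."""
    if len(seq) < 2:
        return 0.0
    return sum(
        1 for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"
    ) / (len(seq) - 1)


@dataclass
class MotifModel:
    """A transcription-factor binding motif as a 4 x w frequency matrix.

    Rows are A, C, G, T; entries may be counts or probabilities. A
    pseudocount is added to every cell before normalizing to column
    probabilities.
    """

    motif_id: str
    name: str
    pfm: np.ndarray
    pseudocount: float = 0.1

    def __post_init__(self) -> None:
        self.pfm = np.asarray(self.pfm, dtype=float)
        if self.pfm.shape[0] != 4:
            raise ValueError("pfm must have 4 rows (A, C, G, T)")
        if self.width < 4:
            raise ValueError("motif width must be >= 4")
        if (self.pfm < 0).any() or (self.pfm.sum(axis=0) <= 0).any():
            raise ValueError("pfm columns must have positive totals")

    @property
    def width(self) -> int:
        return self.pfm.shape[1]

    def probabilities(self) -> np.ndarray:
        p = self.pfm + self.pseudocount
        return p / p.sum(axis=0, keepdims=True)

    def log_odds(self, background: np.ndarray = UNIFORM_BG) -> np.ndarray:
        """5 x w log-likelihood-ratio matrix; row 4 is the N score (the
        background expectation of the column)."""
        bg = np.asarray(background, dtype=float)
        bg = bg / bg.sum()
        llr = np.log2(self.probabilities() / bg[:, None])
        n_row = (bg[:, None] * llr).sum(axis=0, keepdims=True)
        return np.vstack([llr, n_row])

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.pfm.argmax(axis=0))

    @classmethod
    def from_consensus(
        cls, consensus: str, motif_id: str = "M1", name: str = "planted",
        strength: float = 0.9, total: float = 100.0,
    ) -> "MotifModel":
        """Build a sharply peaked PFM around a consensus sequence."""
        consensus = consensus.upper()
        w = len(consensus)
        off = total * (1 - strength) / 3
        pfm = np.full((4, w), off)
        for j, b in enumerate(consensus):
            pfm[_BASE_INDEX[b], j] = total * strength
        return cls(motif_id, name, pfm)


def read_jaspar(path) -> list[MotifModel]:
    """Read a JASPAR-format PFM text file into MotifModel objects."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        pfm = np.array([list(m.counts[b]) for b in BASES], dtype=float)
        out.append(MotifModel(m.matrix_id or m.name, m.name, pfm))
    return out


def write_jaspar(motifs_list: list[MotifModel], path) -> None:
    with open(path, "w") as fh:
        for m in motifs_list:
            fh.write(f">{m.motif_id} {m.name}\n")
            for i, b in enumerate(BASES):
                row = " ".join(f"{v:.2f}" for v in m.pfm[i])
                fh.write(f"{b} [ {row} ]\n")


@dataclass
class PromoterSet:
    """TSS-relative promoter sequences of identical length.

    ``window`` records the convention (default -300..+50 relative to the
    TSS, 350 nt). CpG dinucleotide fractions are computed per promoter.
    """

    sequences: dict[str, str]
    window: tuple[int, int] = (-300, 50)
    flagged: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.sequences = {g: s.upper() for g, s in self.sequences.items()}
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("promoter sequences must all have equal length")
        for g, s in self.sequences.items():
            if set(s) - set("ACGTN"):
                raise ValueError(f"promoter {g} has non-ACGTN characters")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def genes(self) -> list[str]:
        return list(self.sequences)

    def cpg_fractions(self) -> pd.Series:
        return pd.Series(
            {g: cpg_fraction(s) for g, s in self.sequences.items()},
            name="cpg_fraction",
        )

    def subset(self, genes) -> "PromoterSet":
        return PromoterSet(
            {g: self.sequences[g] for g in genes}, self.window,
            self.flagged & set(genes),
        )


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy()


_LUT = np.zeros(128, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _LUT[ord(_b)] = _i


def _indices(seq: str) -> np.ndarray:
    return _LUT[_encode(seq)]


def _window_scores(idx: np.ndarray, llr: np.ndarray) -> np.ndarray:
    """Scores of every placement of the motif (llr: 5 x w) on one strand."""
    w = llr.shape[1]
    if idx.size < w:
        raise ValueError("sequence shorter than motif")
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    return llr[windows, np.arange(w)].sum(axis=-1)


def _batch_best(idx_matrix: np.ndarray, llr: np.ndarray) -> np.ndarray:
    """Best one-strand placement score per row of an index matrix.

    Gathers per-position column scores (n x L x w) once and sums shifted
    diagonals, avoiding a per-window gather.
    """
    n, L = idx_matrix.shape
    w = llr.shape[1]
    if L < w:
        raise ValueError("sequence shorter than motif")
    per_pos = llr[idx_matrix]  # (n, L, w): score of each base at each column
    n_win = L - w + 1
    acc = np.zeros((n, n_win))
    for j in range(w):
        acc += per_pos[:, j : j + n_win, j]
    return acc.max(axis=1)


def score_sequences(
    seqs: list[str], motif: MotifModel, background: np.ndarray = UNIFORM_BG
) -> np.ndarray:
    """Best-hit score in [0, 1] for each sequence.

    The best log-odds score over both strands and all offsets is rescaled
    as ``(score - worst) / (best - worst)`` where worst/best are the sums
    of the per-column minima/maxima of the log-odds matrix.
    """
    llr = motif.log_odds(background)
    best = llr[:4].max(axis=0).sum()
    worst = llr[:4].min(axis=0).sum()
    lengths = {len(s) for s in seqs}
    if len(lengths) == 1 and len(seqs) > 1:
        fwd_idx = np.stack([_indices(s.upper()) for s in seqs])
        rev_idx = np.stack(
            [_indices(reverse_complement(s.upper())) for s in seqs]
        )
        raw = np.maximum(_batch_best(fwd_idx, llr), _batch_best(rev_idx, llr))
        return (raw - worst) / (best - worst)
    out = np.empty(len(seqs))
    for i, s in enumerate(seqs):
        s = s.upper()
        fwd = _window_scores(_indices(s), llr).max()
        rev = _window_scores(_indices(reverse_complement(s)), llr).max()
        out[i] = (max(fwd, rev) - worst) / (best - worst)
    return out


def best_hit_score(
    seq: str, motif: MotifModel, background: np.ndarray = UNIFORM_BG
) -> float:
    """Min-max rescaled best log-odds hit of ``motif`` on ``seq``."""
    return float(score_sequences([seq], motif, background)[0])


@dataclass
class MotifEnrichmentResult:
    motif_id: str
    z: float
    p_value: float
    fg_mean: float
    bg_mean: float
    fg_fraction: float
    bg_fraction: float


def motif_ztest(
    fg: PromoterSet,
    bg: PromoterSet,
    motif: MotifModel,
    score_cutoff: float = 0.8,
    background: np.ndarray | None = None,
) -> MotifEnrichmentResult:
    """One-sided z-test for motif over-representation in the foreground.

    ``z = (mean fg score - mean bg score) / (bg SD / sqrt(|fg|))``; the
    occurrence fractions count promoters whose best-hit score reaches
    ``score_cutoff``. The base background frequencies default to the
    composition of the background promoters.
    """
    if len(bg) < len(fg):
        raise ValueError("background must be at least as large as foreground")
    if background is None:
        background = base_frequencies(bg)
    fg_scores = score_sequences(list(fg.sequences.values()), motif, background)
    bg_scores = score_sequences(list(bg.sequences.values()), motif, background)
    sd = bg_scores.std(ddof=1) if len(bg_scores) > 1 else 0.0
    diff = fg_scores.mean() - bg_scores.mean()
    if sd == 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        z = diff / (sd / np.sqrt(len(fg_scores)))
    p = float(stats.norm.sf(z))
    return MotifEnrichmentResult(
        motif.motif_id,
        float(z),
        p,
        float(fg_scores.mean()),
        float(bg_scores.mean()),
        float((fg_scores >= score_cutoff).mean()),
        float((bg_scores >= score_cutoff).mean()),
    )


def base_frequencies(ps: PromoterSet) -> np.ndarray:
    """A/C/G/T frequencies pooled over a promoter set (N ignored)."""
    counts = np.zeros(4)
    for s in ps.sequences.values():
        idx = _indices(s)
        counts += np.bincount(idx[idx < 4], minlength=4)
    return counts / counts.sum()


def match_background(
    fg: PromoterSet,
    pool: PromoterSet,
    tolerance: float = 0.02,
    rng: np.random.Generator | None = None,
) -> PromoterSet:
    """Sample a CpG-matched background, one pool promoter per fg promoter.

    Sampling is without replacement; each match must agree in CpG
    dinucleotide fraction within ``tolerance``. Raises if the pool is
    exhausted for some foreground promoter.
    """
    rng = rng or np.random.default_rng(0)
    fg_cpg = fg.cpg_fractions()
    pool_cpg = pool.cpg_fractions()
    available = dict(pool_cpg)
    chosen: list[str] = []
    # hardest-to-match first so tight promoters are not starved
    n_cands = {
        g: int((np.abs(pool_cpg - c) <= tolerance).sum())
        for g, c in fg_cpg.items()
    }
    for g in sorted(fg_cpg.index, key=lambda g: n_cands[g]):
        cands = [p for p, c in available.items() if abs(c - fg_cpg[g]) <= tolerance]
        if not cands:
            raise ValueError(
                f"CpG-matched pool exhausted for promoter {g} "
                f"(cpg={fg_cpg[g]:.3f}, tolerance={tolerance})"
            )
        pick = cands[rng.integers(len(cands))]
        available.pop(pick)
        chosen.append(pick)
    return pool.subset(chosen)


def enrich_motifs(
    fg: PromoterSet,
    bg: PromoterSet,
    motifs_list: list[MotifModel],
    score_cutoff: float = 0.8,
) -> pd.DataFrame:
    """z-test every motif; table sorted by ascending p-value."""
    background = base_frequencies(bg)
    rows = []
    for m in motifs_list:
        r = motif_ztest(fg, bg, m, score_cutoff, background)
        rows.append(
            {
                "motif_id": r.motif_id,
                "z": r.z,
                "p_value": r.p_value,
                "fg_mean": r.fg_mean,
                "bg_mean": r.bg_mean,
                "fg_fraction": r.fg_fraction,
                "bg_fraction": r.bg_fraction,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["p_value", "motif_id"], kind="mergesort")
        .reset_index(drop=True)
    )


def extract_promoters(
    tss_bed: pd.DataFrame,
    genome: dict[str, str],
    upstream: int = 300,
    downstream: int = 50,
) -> PromoterSet:
    """Strand-aware promoter extraction around TSS positions.

    ``tss_bed`` needs columns chrom/start/name/strand with 0-based TSS
    coordinates in ``start``. Plus-strand promoters cover
    ``[tss - upstream, tss + downstream)``; minus-strand promoters are the
    reverse complement of ``[tss - downstream, tss + upstream)``. Windows
    running past a contig edge are padded with N and the gene flagged.
    """
    sequences: dict[str, str] = {}
    flagged: set[str] = set()
    for row in tss_bed.itertuples(index=False):
        chrom_seq = genome[row.chrom].upper()
        tss = int(row.start)
        if row.strand == "+":
            lo, hi = tss - upstream, tss + downstream
        elif row.strand == "-":
            lo, hi = tss - downstream, tss + upstream
        else:
            raise ValueError(f"bad strand {row.strand!r} for {row.name}")
        pad_left = max(0, -lo)
        pad_right = max(0, hi - len(chrom_seq))
        seq = (
            "N" * pad_left
            + chrom_seq[max(lo, 0) : min(hi, len(chrom_seq))]
            + "N" * pad_right
        )
        if row.strand == "-":
            seq = reverse_complement(seq)
        if pad_left or pad_right:
            flagged.add(row.name)
        sequences[row.name] = seq
    return PromoterSet(sequences, (-upstream, downstream), flagged)
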