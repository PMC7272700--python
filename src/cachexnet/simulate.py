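"""Synthetic paired miRNA/mRNA study generator with planted ground truth.

Emulates the statistical structure of a two-group (4 control vs 6 case)
bulk RNA-seq study of wasting muscle: negative-binomial counts with
per-sample library sizes, a minority of DE genes split into four blocks
(up/down x uniformly/variably regulated, sized after the four expression-
stability clusters of the study design), DE miRNAs anti-correlated with
planted target genes, promoters carrying a planted motif in the
up-regulated block, per-source target-prediction tables with decoys, and
binary images of known fractal dimension. Every generator is driven by a
child seed derived from one global seed, so each input can be regenerated
independently and byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motifs import BASES, MotifModel, PromoterSet, reverse_complement
from .normalize import CASE, CONTROL, CountMatrix

#: relative sizes of the four DE blocks: up-variable, up-uniform,
#: down-variable, down-uniform (386/101/157/364 of 1008 in the emulated
#: study design)
BLOCK_FRACTIONS = {
    ("up", "variable"): 386 / 1008,
    ("up", "uniform"): 101 / 1008,
    ("down", "variable"): 157 / 1008,
    ("down", "uniform"): 364 / 1008,
}

_CHILD = {"counts": 0, "promoters": 1, "targets": 2, "images": 3, "genesets": 4}


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-generator child RNG from the global seed."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_CHILD[stream],))
    return np.random.default_rng(ss)


@dataclass
class SimulationConfig:
    """Study-level simulation parameters.

    Defaults mirror the emulated design: 4 control vs 6 case samples,
    ~10% DE genes at a 3-fold mean effect (|log2 FC| = 1.585), small
    per-sample log2 FC scatter for uniformly regulated genes (0.15) and
    large scatter for variably regulated ones (0.8), NB dispersion 0.05,
    and 18-of-300 DE miRNAs (13 up / 5 down, as in the study).
    """

    seed: int = 0
    n_control: int = 4
    n_case: int = 6
    n_genes: int = 2000
    n_mirnas: int = 300
    frac_de: float = 0.10
    frac_de_mirna: float = 0.06
    lfc_mean: float = 1.585
    lfc_sd_uniform: float = 0.15
    lfc_sd_variable: float = 0.8
    dispersion: float = 0.05
    library_size_range: tuple[float, float] = (5e5, 2e6)
    frac_targets_true: float = 0.05
    motif_plant_rate: float = 0.8

    def __post_init__(self) -> None:
        for name in ("seed", "n_control", "n_case", "n_genes", "n_mirnas"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")
            setattr(self, name, int(v))
        if self.n_control < 2 or self.n_case < 2:
            raise ValueError("need >= 2 samples per group")
        if not 0 <= self.frac_de < 0.5:
            raise ValueError("frac_de must be in [0, 0.5)")
        if not 0 <= self.frac_de_mirna < 0.5:
            raise ValueError("frac_de_mirna must be in [0, 0.5)")
        for name in ("lfc_sd_uniform", "lfc_sd_variable", "dispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must be positive and ordered")
        for name in ("frac_targets_true", "motif_plant_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted simulation truth consumed by recovery tests."""

    de_status: pd.Series
    regulation_class: pd.Series
    true_log2fc: pd.DataFrame
    mirna_de_status: pd.Series
    mirna_true_log2fc: pd.DataFrame
    target_pairs: set[tuple[str, str]]
    planted_motif_genes: set[str] = field(default_factory=set)
    subgroup_samples: list[str] | None = None
    image_true_dimension: float | None = None

    def genes_of(self, status: str, regulation: str | None = None) -> list[str]:
        mask = self.de_status == status
        if regulation is not None:
            mask &= self.regulation_class == regulation
        return list(self.de_status.index[mask])


def _sample_names(config: SimulationConfig) -> tuple[list[str], list[str]]:
    controls = [f"C{i + 1}" for i in range(config.n_control)]
    cases = [f"L{i + 1}" for i in range(config.n_case)]
    return controls, cases


def _nb_counts(mu: np.ndarray, dispersion: float, rng) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mu))


def simulate_paired_counts(
    config: SimulationConfig,
    subgroup_mode: bool = False,
    n_subgroup: int = 3,
    subgroup_attenuation: float = 0.3,
) -> tuple[CountMatrix, CountMatrix, GroundTruth]:
    """Generate paired mRNA and miRNA NB count matrices plus ground truth.

    Counts are NB(mean = size_factor_s * baseline_g * 2**lfc_{g,s},
    dispersion) with variance mu + alpha mu^2. Uniform-class DE genes draw
    their per-case-sample log2 FC with SD ``lfc_sd_uniform``, variable-
    class with ``lfc_sd_variable``; null genes have log2 FC 0. Each
    planted (miRNA, gene) target pair has opposite effect signs. With
    ``subgroup_mode`` the variable-class effect becomes structured rather
    than noisy: responder case samples get a strong response (amplitude
    ``lfc_mean + lfc_sd_variable``) while ``n_subgroup`` case samples
    (L2..L4 by default) respond at only ``subgroup_attenuation`` of the
    nominal effect and therefore sit near the controls, emulating the
    near-control sample subgroup of the study.
    """
    rng = child_rng(config.seed, "counts")
    controls, cases = _sample_names(config)
    samples = controls + cases
    genes = [f"gene{i + 1:05d}" for i in range(config.n_genes)]
    mirnas = [f"mir-{i + 1:04d}" for i in range(config.n_mirnas)]
    if subgroup_mode and config.n_case <= n_subgroup:
        raise ValueError("subgroup_mode needs n_case > n_subgroup")
    subgroup = cases[1 : 1 + n_subgroup] if subgroup_mode else None

    # --- assign gene DE blocks ---
    n_de = int(round(config.frac_de * config.n_genes))
    de_genes = list(rng.choice(genes, size=n_de, replace=False))
    sizes = {}
    assigned = 0
    blocks = list(BLOCK_FRACTIONS)
    for key in blocks[:-1]:
        sizes[key] = int(round(BLOCK_FRACTIONS[key] * n_de))
        assigned += sizes[key]
    sizes[blocks[-1]] = n_de - assigned
    de_status = pd.Series("null", index=genes, name="de_status")
    reg_class = pd.Series(pd.NA, index=genes, name="regulation_class", dtype=object)
    pos = 0
    for (direction, regulation), size in sizes.items():
        for g in de_genes[pos : pos + size]:
            de_status[g] = direction
            reg_class[g] = regulation
        pos += size

    # --- per-case-sample true log2 fold changes ---
    lfc = pd.DataFrame(0.0, index=genes, columns=cases)
    responders = [s for s in cases if subgroup is None or s not in subgroup]
    for g in de_genes:
        sign = 1.0 if de_status[g] == "up" else -1.0
        if reg_class[g] == "uniform":
            lfc.loc[g] = sign * config.lfc_mean + rng.normal(
                0, config.lfc_sd_uniform, config.n_case
            )
        elif subgroup_mode:
            # structured variability: a strong response in the responder
            # samples (amplitude lfc_mean + lfc_sd_variable) and a weak,
            # attenuated response in the subgroup samples, which therefore
            # sit near the controls
            vals = pd.Series(0.0, index=cases)
            vals[responders] = sign * (
                config.lfc_mean + config.lfc_sd_variable
            ) + rng.normal(0, config.lfc_sd_uniform, len(responders))
            sub_samples = [s for s in cases if s not in responders]
            vals[sub_samples] = sign * subgroup_attenuation * config.lfc_mean + (
                rng.normal(0, config.lfc_sd_uniform, len(sub_samples))
            )
            lfc.loc[g] = vals
        else:
            lfc.loc[g] = sign * config.lfc_mean + rng.normal(
                0, config.lfc_sd_variable, config.n_case
            )

    # --- mRNA counts ---
    baseline = rng.lognormal(np.log(100), 1.0, config.n_genes)
    lo, hi = config.library_size_range
    libsizes = np.exp(rng.uniform(np.log(lo), np.log(hi), len(samples)))
    size_factors = libsizes / np.exp(np.mean(np.log(libsizes)))
    mu = baseline[:, None] * size_factors[None, :]
    mu[:, config.n_control:] *= 2.0 ** lfc.values
    counts = _nb_counts(mu, config.dispersion, rng)
    lengths = pd.Series(rng.integers(500, 5000, config.n_genes), index=genes)
    groups = pd.Series(
        [CONTROL] * config.n_control + [CASE] * config.n_case, index=samples
    )
    cm_mrna = CountMatrix(
        pd.DataFrame(counts, index=genes, columns=samples), groups, lengths
    )

    # --- miRNA DE assignment (13/18 up, as in the study) ---
    n_de_mir = int(round(config.frac_de_mirna * config.n_mirnas))
    n_up_mir = int(round(n_de_mir * 13 / 18))
    de_mirs = list(rng.choice(mirnas, size=n_de_mir, replace=False))
    mir_status = pd.Series("null", index=mirnas, name="de_status")
    for m in de_mirs[:n_up_mir]:
        mir_status[m] = "up"
    for m in de_mirs[n_up_mir:]:
        mir_status[m] = "down"
    mir_lfc = pd.DataFrame(0.0, index=mirnas, columns=cases)
    for m in de_mirs:
        sign = 1.0 if mir_status[m] == "up" else -1.0
        mir_lfc.loc[m] = sign * config.lfc_mean + rng.normal(
            0, config.lfc_sd_uniform, config.n_case
        )

    # --- miRNA counts; DE miRNAs drawn well above the expression floor ---
    mir_base = rng.lognormal(np.log(60), 1.8, config.n_mirnas)
    de_idx = [mirnas.index(m) for m in de_mirs]
    mir_base[de_idx] = rng.lognormal(np.log(400), 0.8, n_de_mir)
    mir_libs = np.exp(rng.uniform(np.log(lo / 10), np.log(hi / 10), len(samples)))
    mir_sf = mir_libs / np.exp(np.mean(np.log(mir_libs)))
    mir_mu = mir_base[:, None] * mir_sf[None, :]
    mir_mu[:, config.n_control:] *= 2.0 ** mir_lfc.values
    mir_counts = _nb_counts(mir_mu, config.dispersion, rng)
    cm_mirna = CountMatrix(
        pd.DataFrame(mir_counts, index=mirnas, columns=samples), groups
    )

    # --- true regulatory couplings: opposite-sign pairs only ---
    target_pairs: set[tuple[str, str]] = set()
    for m in de_mirs:
        opposite = "down" if mir_status[m] == "up" else "up"
        pool = [g for g in de_genes if de_status[g] == opposite]
        hit = rng.random(len(pool)) < config.frac_targets_true
        target_pairs.update((m, g) for g, h in zip(pool, hit) if h)

    truth = GroundTruth(
        de_status=de_status,
        regulation_class=reg_class,
        true_log2fc=lfc,
        mirna_de_status=mir_status,
        mirna_true_log2fc=mir_lfc,
        target_pairs=target_pairs,
        subgroup_samples=list(subgroup) if subgroup else None,
    )
    return cm_mrna, cm_mirna, truth


def simulate_promoters(
    genes: list[str],
    fg_genes: set[str],
    motif: MotifModel,
    config: SimulationConfig,
    length: int = 350,
    gc: float = 0.42,
) -> tuple[PromoterSet, set[str]]:
    """Random promoters with the motif consensus planted in ``fg_genes``.

    Each promoter is ``length`` nt of i.i.d. bases at the given GC
    content; each foreground gene receives one exact consensus instance at
    a uniform position with probability ``motif_plant_rate``. Returns the
    promoter set and the genes actually planted.
    """
    if motif.width > length:
        raise ValueError("motif longer than promoter")
    rng = child_rng(config.seed, "promoters")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    consensus = motif.consensus
    sequences: dict[str, str] = {}
    planted: set[str] = set()
    for g in genes:
        seq = "".join(
            np.array(list(BASES))[rng.choice(4, size=length, p=p)]
        )
        if g in fg_genes and rng.random() < config.motif_plant_rate:
            pos = rng.integers(0, length - motif.width + 1)
            seq = seq[:pos] + consensus + seq[pos + motif.width:]
            planted.add(g)
        sequences[g] = seq
    return PromoterSet(sequences, (-300, 50)), planted


def embed_promoters_in_genome(
    ps: PromoterSet,
    config: SimulationConfig,
    spacer: int = 60,
    upstream: int = 300,
    downstream: int = 50,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Lay promoters on a synthetic chromosome with alternating strands.

    Returns the genome (single contig ``chrS``) and a TSS BED table
    (0-based) such that strand-aware extraction with the same window
    recovers every promoter exactly.
    """
    rng = child_rng(config.seed, "promoters")  # independent draw order is fine
    parts: list[str] = []
    rows = []
    cursor = 0
    for i, (gene, seq) in enumerate(ps.sequences.items()):
        gap = "".join(
            np.array(list(BASES))[rng.integers(0, 4, size=spacer)]
        )
        parts.append(gap)
        cursor += spacer
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            parts.append(seq)
            tss = cursor + upstream
        else:
            parts.append(reverse_complement(seq))
            tss = cursor + downstream
        cursor += len(seq)
        rows.append(
            {"chrom": "chrS", "start": tss, "end": tss + 1,
             "name": gene, "score": 0, "strand": strand}
        )
    genome = {"chrS": "".join(parts)}
    return genome, pd.DataFrame(rows)


@dataclass
class TargetMap:
    """Per-source miRNA->gene prediction pairs with validated flags."""

    sources: dict[str, set[tuple[str, str]]]
    validated: set[str] = field(default_factory=set)

    def union(self) -> set[tuple[str, str]]:
        out: set[tuple[str, str]] = set()
        for pairs in self.sources.values():
            out |= pairs
        return out


def simulate_target_tables(
    truth: GroundTruth,
    config: SimulationConfig,
    n_sources: int = 4,
    decoy_rate: float = 0.5,
) -> TargetMap:
    """Prediction tables whose union covers the truth, plus decoys.

    Every true pair is assigned to a non-empty random subset of the
    prediction sources and, with probability 0.3, also to the validated
    table. Decoy pairs -- a DE miRNA paired with a *non-DE* gene, so the
    downstream anti-correlation filter must remove all of them -- are
    added at ``decoy_rate`` per true pair into one random prediction
    source.
    """
    rng = child_rng(config.seed, "targets")
    names = [f"pred{i + 1}" for i in range(n_sources)]
    sources: dict[str, set] = {n: set() for n in names}
    sources["validated"] = set()
    for pair in sorted(truth.target_pairs):
        members = [n for n in names if rng.random() < 0.5]
        if not members:
            members = [names[rng.integers(n_sources)]]
        for n in members:
            sources[n].add(pair)
        if rng.random() < 0.3:
            sources["validated"].add(pair)
    null_genes = truth.genes_of("null")
    de_mirs = list(
        truth.mirna_de_status.index[truth.mirna_de_status != "null"]
    )
    n_decoys = int(round(decoy_rate * len(truth.target_pairs)))
    decoys: set[tuple[str, str]] = set()
    while len(decoys) < n_decoys and de_mirs and null_genes:
        pair = (
            de_mirs[rng.integers(len(de_mirs))],
            null_genes[rng.integers(len(null_genes))],
        )
        if pair not in truth.target_pairs:
            decoys.add(pair)
    for pair in sorted(decoys):
        sources[names[rng.integers(n_sources)]].add(pair)
    return TargetMap(sources, validated={"validated"})


def simulate_gene_sets(
    truth: GroundTruth,
    config: SimulationConfig,
    n_random_terms: int = 30,
    term_size_range: tuple[int, int] = (10, 60),
) -> dict[str, tuple[str, set[str]]]:
    """A GMT-style collection with planted up/down terms plus noise terms."""
    rng = child_rng(config.seed, "genesets")
    universe = list(truth.de_status.index)
    up = truth.genes_of("up")
    down = truth.genes_of("down")
    terms: dict[str, tuple[str, set[str]]] = {}
    if up:
        k = min(len(up), 40)
        terms["TERM_UP"] = (
            "planted up-regulated module",
            set(rng.choice(up, size=k, replace=False)),
        )
    if down:
        k = min(len(down), 40)
        terms["TERM_DOWN"] = (
            "planted down-regulated module",
            set(rng.choice(down, size=k, replace=False)),
        )
    lo, hi = term_size_range
    for i in range(n_random_terms):
        size = int(rng.integers(lo, hi + 1))
        genes = set(rng.choice(universe, size=size, replace=False))
        terms[f"TERM_R{i + 1:03d}"] = (f"random term {i + 1}", genes)
    return terms


def sierpinski_carpet(depth: int) -> np.ndarray:
    """3^d x 3^d boolean carpet with 8^d foreground pixels."""
    if depth < 0:
        raise ValueError("depth must be >= 0")
    tile = np.ones((3, 3), dtype=bool)
    tile[1, 1] = False
    img = np.ones((1, 1), dtype=bool)
    for _ in range(depth):
        img = np.kron(img, tile)
    return img


def simulate_fractal_image(
    kind: str,
    depth_or_size: int,
    area_fraction: float = 0.25,
    rng: np.random.Generator | None = None,
):
    """Binary fixture images with known fractal dimension.

    ``filled``: all-foreground square (D = 2); ``sierpinski_carpet``:
    depth-d carpet (D = log 8 / log 3); ``random_fiber``: anisotropically
    smoothed noise thresholded at the requested foreground fraction,
    mimicking a stained-fiber micrograph (plane-filling, D = 2).
    """
    from .histology import BinaryImage

    if kind == "filled":
        mask = np.ones((depth_or_size, depth_or_size), dtype=bool)
        return BinaryImage(mask, source_id="filled"), 2.0
    if kind == "sierpinski_carpet":
        mask = sierpinski_carpet(depth_or_size)
        return BinaryImage(mask, source_id=f"carpet{depth_or_size}"), float(
            np.log(8) / np.log(3)
        )
    if kind == "random_fiber":
        from scipy import ndimage

        rng = rng or np.random.default_rng(0)
        noise = rng.normal(size=(depth_or_size, depth_or_size))
        smooth = ndimage.gaussian_filter(noise, sigma=(depth_or_size / 40, 2))
        thresh = np.quantile(smooth, 1 - area_fraction)
        return BinaryImage(smooth > thresh, source_id="fiber"), 2.0
    raise ValueError(f"unknown image kind {kind!r}")
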