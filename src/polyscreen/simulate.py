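"""Synthetic inputs with programmed ground truth.

Two generators, each seeded and deterministic:

* :func:`simulate_screen` — paired amplicon reads for a codon-randomized
  editing screen sampled over a time course. Edited cells carry one of the
  64 codons at the randomized position; each codon's abundance evolves as
  deterministic exponential growth ``a_c(t) = a_c(t0) * w_c**(t - t0)``
  (renormalized) with relative growth rate ``w_c`` per day, then read
  counts are multinomial at the configured depth. Reads are error-free.
  Unedited molecules (no tag bases) are emitted at ``1 - editing_fraction``.

* :func:`simulate_polycistrome` — a polycistronic genome in which genes
  close to a transcription start-site are transcriptionally depressed in
  the "mutant" condition: per-gene true effect
  ``log2FC = -beta * max(0, 1 - d_TSS / window) + Normal(0, sigma)``.
  Replicate log2 abundances are drawn per condition, a per-gene Welch t
  plus Benjamini-Hochberg correction yields the FDR column, and the truth
  table records distances and junction classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._genetics import CODONS, revcomp
from .counting import AmpliconDesign
from .polycistron import PolycistronMap, build_map, gene_context


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------- screen

@dataclass
class ScreenSimConfig:
    """Study conditions for the editing-screen simulator.

    Defaults mirror a two-library screen sampled 0.5, 2, 4 and 6 days after
    template delivery. ``codon_fitness`` maps each codon to a relative
    growth rate per day (1.0 = neutral; 0 = lethal, e.g. nonsense codons).
    ``editing_fraction`` is the fraction of molecules carrying the edit at
    the first timepoint; the bulk edited fraction is not knowable a priori
    and 0.5 is a mid-range default.
    """

    codon_fitness: dict[str, float]
    target_positions: tuple[str, ...] = ("K4",)
    timepoints_days: tuple[float, ...] = (0.5, 2.0, 4.0, 6.0)
    editing_fraction: float = 0.5
    depth: int = 50_000
    replicates: int = 2
    read_length: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in CODONS if c not in self.codon_fitness]
        if missing:
            raise SimulationError(f"fitness map missing codons: {missing[:4]}...")
        if any(w < 0 for w in self.codon_fitness.values()):
            raise SimulationError("fitness values must be >= 0")
        if self.depth <= 0:
            raise SimulationError("depth must be positive")
        if list(self.timepoints_days) != sorted(set(self.timepoints_days)):
            raise SimulationError("timepoints must be strictly increasing")
        if not 0 <= self.editing_fraction <= 1:
            raise SimulationError("editing_fraction must be in [0, 1]")
        if self.replicates < 1:
            raise SimulationError("replicates must be >= 1")


def codon_frequencies(
    config: ScreenSimConfig, day: float, initial: np.ndarray | None = None
) -> np.ndarray:
    """True codon frequency vector at ``day`` (sums to 1).

    Starts uniform over the 64 codons at the first timepoint unless
    ``initial`` is given; abundances grow as ``w**(day - t0)`` and are
    renormalized. Lethal codons (w = 0) vanish for day > t0.
    """
    t0 = config.timepoints_days[0]
    w = np.array([config.codon_fitness[c] for c in CODONS], dtype=float)
    a0 = np.full(len(CODONS), 1 / len(CODONS)) if initial is None else initial
    with np.errstate(divide="ignore"):
        a = a0 * np.power(w, day - t0)
    total = a.sum()
    if total <= 0:
        raise SimulationError(f"all codon abundances zero at day {day}")
    return a / total


@dataclass
class ScreenSim:
    """Simulated screen: reads, manifest and ground truth."""

    samples: dict[str, list[tuple[str, str]]]
    manifest: pd.DataFrame
    truth: pd.DataFrame
    design: AmpliconDesign
    config: ScreenSimConfig


def _amplicon_reads(amplicon: str, read_length: int) -> tuple[str, str]:
    r1 = amplicon[:read_length]
    r2 = revcomp(amplicon[-read_length:])
    return r1, r2


def simulate_screen(config: ScreenSimConfig, design: AmpliconDesign) -> ScreenSim:
    """Generate paired reads for every (position, replicate, timepoint).

    Each sample draws ``depth`` pairs: edited pairs (binomial at
    ``editing_fraction``) carry a codon multinomially sampled from the true
    frequency vector of that day and include the tag bases; unedited pairs
    come from the tag-free allele. Byte-identical for a fixed seed.
    """
    if design.unedited_sequence is None:
        raise SimulationError("design needs unedited_sequence for the unedited fraction")
    rng = np.random.default_rng(config.seed)
    amp = design.amplicon_sequence
    o = design.codon_offset
    variant_pairs = [
        _amplicon_reads(amp[:o] + c + amp[o + 3 :], config.read_length) for c in CODONS
    ]
    unedited_pair = _amplicon_reads(design.unedited_sequence, config.read_length)

    samples: dict[str, list[tuple[str, str]]] = {}
    manifest_rows = []
    truth_rows = []
    for pos in config.target_positions:
        for day in config.timepoints_days:
            freqs = codon_frequencies(config, day)
            for c, f in zip(CODONS, freqs):
                truth_rows.append(
                    {"position": pos, "day": day, "codon": c, "true_freq": f}
                )
            for rep in range(1, config.replicates + 1):
                sample_id = f"{pos}_L{rep}_d{day:g}"
                n_edited = rng.binomial(config.depth, config.editing_fraction)
                codon_counts = rng.multinomial(n_edited, freqs)
                pairs = [unedited_pair] * (config.depth - n_edited)
                for ci, n in enumerate(codon_counts):
                    pairs.extend([variant_pairs[ci]] * int(n))
                order = rng.permutation(len(pairs))
                samples[sample_id] = [pairs[i] for i in order]
                manifest_rows.append(
                    {"sample_id": sample_id, "library": f"{pos}_L{rep}",
                     "day": day, "replicate": rep}
                )
    return ScreenSim(
        samples=samples,
        manifest=pd.DataFrame(manifest_rows),
        truth=pd.DataFrame(truth_rows),
        design=design,
        config=config,
    )


def neutral_fitness(lethal_stops: bool = False) -> dict[str, float]:
    """Fitness map with every codon neutral (optionally lethal stops)."""
    from ._genetics import STOP_CODONS

    fit = {c: 1.0 for c in CODONS}
    if lethal_stops:
        for c in STOP_CODONS:
            fit[c] = 0.0
    return fit


def example_amplicon_design(
    seed: int = 0, length: int = 217, codon_offset: int = 60, k: int = 12
) -> AmpliconDesign:
    """A synthetic amplicon target for simulations and tests.

    Random sequence of the configured length with a randomized codon placed
    within the first mate of a 100-b paired-end read (as in a short edited
    amplicon) and two synonymous-style tag substitutions next to it; the
    unedited allele reverts the tags and carries the wild-type AAG codon.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seq = "".join(rng.choice(bases, size=length))
    # introduce tag differences 6 and 9 bp downstream of the codon
    tag_offsets = (codon_offset + 9, codon_offset + 12)
    unedited = list(seq)
    for p in tag_offsets:
        unedited[p] = {"A": "G", "C": "T", "G": "A", "T": "C"}[seq[p]]
    unedited = "".join(unedited)
    edited = seq[:codon_offset] + "AAG" + seq[codon_offset + 3 :]
    unedited = unedited[:codon_offset] + "AAG" + unedited[codon_offset + 3 :]
    return AmpliconDesign.from_amplicon(
        edited, codon_offset, tag_offsets=tag_offsets, k=k, unedited_sequence=unedited
    )


def write_screen_fastq(sim: ScreenSim, outdir: str | Path) -> pd.DataFrame:
    """Write gzipped FASTQ pairs plus a manifest TSV; returns the manifest."""
    import gzip

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = sim.manifest.copy()
    paths1, paths2 = [], []
    for sample_id, pairs in sim.samples.items():
        p1 = outdir / f"{sample_id}_R1.fastq.gz"
        p2 = outdir / f"{sample_id}_R2.fastq.gz"
        with gzip.open(p1, "wt") as h1, gzip.open(p2, "wt") as h2:
            for i, (r1, r2) in enumerate(pairs):
                h1.write(f"@{sample_id}.{i}/1\n{r1}\n+\n{'I' * len(r1)}\n")
                h2.write(f"@{sample_id}.{i}/2\n{r2}\n+\n{'I' * len(r2)}\n")
        paths1.append(str(p1))
        paths2.append(str(p2))
    manifest["fastq_1"] = paths1
    manifest["fastq_2"] = paths2
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    sim.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return manifest


# ---------------------------------------------------------- polycistrome

@dataclass
class GenomeSimConfig:
    """Study conditions for the polycistronic-genome simulator.

    Defaults emulate the scale of a trypanosomatid RNA polymerase II
    transcriptome: tens of polycistrons of ~50 genes, first genes a few kbp
    from the start-site, and a promoter-proximal depression of
    ``effect_size_beta`` log2 units decaying linearly to zero across
    ``effect_window`` bp.
    """

    n_polycistrons: int = 40
    genes_per_unit: float = 50.0
    gene_length: float = 1_500.0
    gene_spacing: float = 1_000.0
    first_gene_offset: float = 2_700.0
    junction_mix: dict[str, float] = field(
        default_factory=lambda: {"divergent": 0.3, "convergent": 0.3, "tandem": 0.4}
    )
    intergenic_gap: float = 5_000.0
    effect_size_beta: float = 0.5
    effect_window: int = 10_000
    sigma: float = 0.25
    dispersion: float = 0.3
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_polycistrons, self.genes_per_unit, self.gene_length,
               self.gene_spacing, self.n_replicates) <= 0:
            raise SimulationError("counts and sizes must be positive")
        if self.effect_window <= 0:
            raise SimulationError("effect_window must be positive")
        total = sum(self.junction_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError("junction proportions must sum to 1")
        if self.sigma < 0 or self.dispersion < 0:
            raise SimulationError("sigma and dispersion must be >= 0")


@dataclass
class PolycistromeSim:
    """Simulated polycistronic genome with a promoter-proximal defect."""

    pmap: PolycistronMap
    genes: pd.DataFrame
    tss_sites: pd.DataFrame
    tts_sites: pd.DataFrame
    de_table: pd.DataFrame
    truth: pd.DataFrame
    contexts: pd.DataFrame
    config: GenomeSimConfig


def _draw_strand_chain(rng: np.random.Generator, n: int, mix: dict[str, float]) -> list[str]:
    """Unit strands whose junctions follow the configured class mix.

    Junction class is a deterministic function of consecutive strands:
    (-,+) divergent, (+,-) convergent, equal strands tandem. Divergent and
    convergent junctions necessarily alternate along a chromosome, so their
    achievable proportions are equal; the chain keeps the strand with
    probability ``mix['tandem']`` and flips it otherwise, which realizes
    the tandem fraction exactly and splits the remainder evenly between
    divergent and convergent.
    """
    strands = [rng.choice(["+", "-"])]
    p_keep = mix["tandem"]
    for _ in range(n - 1):
        keep = rng.random() < p_keep
        strands.append(strands[-1] if keep else ("-" if strands[-1] == "+" else "+"))
    return strands


def simulate_polycistrome(config: GenomeSimConfig) -> PolycistromeSim:
    """Build genome, annotation, truth and differential table in one pass."""
    rng = np.random.default_rng(config.seed)
    strands = _draw_strand_chain(rng, config.n_polycistrons, config.junction_mix)

    chrom = "chr1"
    cursor = int(rng.integers(1_000, 5_000))
    gene_rows = []
    tss_rows, tts_rows = [], []
    gid = 0
    for ui, strand in enumerate(strands):
        n_genes = max(1, int(rng.poisson(config.genes_per_unit)))
        offsets = []  # transcription-direction offset of each gene 5' end
        pos = rng.exponential(config.first_gene_offset)
        lengths = rng.gamma(4.0, config.gene_length / 4.0, size=n_genes)
        for gi in range(n_genes):
            offsets.append(pos)
            pos += lengths[gi] + rng.exponential(config.gene_spacing)
        unit_len = int(pos + rng.exponential(config.first_gene_offset))
        unit_start = cursor
        unit_end = unit_start + unit_len
        if strand == "+":
            tss, tts = unit_start, unit_end
        else:
            tss, tts = unit_end, unit_start
        tss_rows.append({"chrom": chrom, "start": tss, "end": tss + 1,
                         "name": f"TSS{ui + 1:03d}", "score": 0, "strand": strand})
        tts_rows.append({"chrom": chrom, "start": tts, "end": tts + 1,
                         "name": f"TTS{ui + 1:03d}", "score": 0, "strand": strand})
        for gi in range(n_genes):
            gid += 1
            off = int(offsets[gi])
            ln = max(150, int(lengths[gi]))
            if strand == "+":
                start = unit_start + off
                end = start + ln
            else:
                end = unit_end - off
                start = end - ln
            start = max(unit_start, start)
            end = min(unit_end, end)
            gene_rows.append(
                {"gene_id": f"g{gid:05d}", "chrom": chrom, "start": start,
                 "end": end, "strand": strand}
            )
        cursor = unit_end + int(rng.exponential(config.intergenic_gap)) + 1_000

    genes = pd.DataFrame(gene_rows)
    tss_sites = pd.DataFrame(tss_rows)
    tts_sites = pd.DataFrame(tts_rows)
    pmap = build_map(tss_sites, tts_sites)
    contexts = gene_context(pmap, genes, window=config.effect_window)

    d_tss = contexts.d_tss.to_numpy(dtype=float)
    ramp = np.maximum(0.0, 1.0 - d_tss / config.effect_window)
    true_lfc = -config.effect_size_beta * ramp + rng.normal(
        0.0, config.sigma, size=len(genes)
    )

    # replicate log2 abundances and a per-gene Welch t + BH FDR
    mu = rng.normal(8.0, 2.0, size=len(genes))
    n_rep = config.n_replicates
    ctrl = rng.normal(mu[:, None], config.dispersion, size=(len(genes), n_rep))
    mut = rng.normal(
        (mu + true_lfc)[:, None], config.dispersion, size=(len(genes), n_rep)
    )
    t, p = stats.ttest_ind(mut, ctrl, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    fdr = multipletests(p, method="fdr_bh")[1]
    de_table = pd.DataFrame(
        {
            "feature_id": genes.gene_id,
            "log2fc": mut.mean(axis=1) - ctrl.mean(axis=1),
            "fdr": fdr,
        }
    )
    truth = contexts[["gene_id", "d_tss", "d_tts", "tss_class", "tts_class"]].copy()
    truth["true_log2fc"] = true_lfc
    truth["p_raw"] = p
    return PolycistromeSim(
        pmap=pmap,
        genes=genes,
        tss_sites=tss_sites,
        tts_sites=tts_sites,
        de_table=de_table,
        truth=truth,
        contexts=contexts,
        config=config,
    )


def recover_beta(sim: PolycistromeSim) -> float:
    """Estimate the promoter-proximity effect size from measured log2FC.

    Least-squares regression of the differential table's log2fc on the
    linear proximity ramp ``max(0, 1 - d_TSS/window)`` (with intercept);
    the negated slope estimates beta.
    """
    merged = sim.de_table.merge(
        sim.truth[["gene_id", "d_tss"]], left_on="feature_id", right_on="gene_id"
    )
    ramp = np.maximum(0.0, 1.0 - merged.d_tss / sim.config.effect_window)
    X = np.column_stack([np.ones(len(ramp)), ramp])
    coef, *_ = np.linalg.lstsq(X, merged.log2fc.to_numpy(), rcond=None)
    return float(-coef[1])
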