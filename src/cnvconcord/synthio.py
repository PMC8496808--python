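"""Synthetic two-species CNV study generator with recorded ground truth.

Emulates the structure of an inter-species array-CGH experiment backed by
genome assemblies from two sequencing platforms:

* two species genomes sharing gene content but differing by planted
  segmental duplications (gene families at independently drawn copy
  numbers per species),
* per species a "long-read-like" assembly (the genome verbatim) and a
  "short-read-like" assembly in which near-identical multi-copy families
  may be collapsed to a single representative copy,
* a probe set with three probes per gene plus intergenic probes at a
  fixed genomic spacing, designed on the species-A sequence (mirroring a
  single-reference array design bias),
* four two-channel arrays (three biological samples, one of which is
  hybridised twice as a technical replicate) whose log2 ratios reflect
  the true copy ratio plus optional GC-dependent bias and Gaussian noise,
* a flat gene -> GO-term annotation with optionally enriched terms among
  CNV genes.

Every planted quantity is recorded in a truth table so downstream
recovery can be scored exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import gc_fraction, mutate, random_dna, stage_rng
from .exceptions import ConfigError, ProbeDesignError, SizingError

ARRAY_IDS = ("Bio1", "Bio2", "Bio3-TechA", "Bio3-TechB")
#: replicate design: the technical pair is averaged, then the median is
#: taken of that mean and the two remaining biological arrays.
DEFAULT_DESIGN = {"tech_pair": ("Bio3-TechA", "Bio3-TechB"), "bio": ("Bio1", "Bio2")}

SPECIES_A = "speciesA"
SPECIES_B = "speciesB"


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    ``genome_length`` is the length of the single-copy backbone; the
    emitted genomes are longer by the extra copies of planted families.
    """

    seed: int = 0
    genome_length: int = 400_000
    n_genes: int = 40
    gene_length: int = 300
    probe_length: int = 60
    probes_per_gene: int = 3
    intergenic_spacing: int = 6000
    n_cnv_regions: int = 20
    copy_range_a: tuple[int, int] = (1, 6)
    copy_range_b: tuple[int, int] = (1, 6)
    collapse_probability: float = 0.5
    divergence_rate: float = 0.0
    noise_sd: float = 0.3
    gc_bias_coeff: float = 0.0
    intra_species_cnv_rate: float = 0.0
    copy_linker_length: int = 50

    def __post_init__(self) -> None:
        if self.probe_length >= self.gene_length:
            raise ConfigError("probe_length must be smaller than gene_length")
        for name in ("collapse_probability", "divergence_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        for name in ("copy_range_a", "copy_range_b"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ConfigError(f"{name} must satisfy 1 <= lo <= hi")
        if self.n_cnv_regions > self.n_genes:
            raise ConfigError("n_cnv_regions cannot exceed n_genes")
        if self.intra_species_cnv_rate < 0 or self.intra_species_cnv_rate > 1:
            raise ConfigError("intra_species_cnv_rate must lie in [0, 1]")


@dataclass(frozen=True)
class Block:
    """One building block of a genome: intergenic spacer, gene copy or linker."""

    kind: str  # "spacer" | "gene" | "linker"
    seq: str
    gene_id: str | None = None
    copy_index: int = 0
    spacer_index: int | None = None


@dataclass
class Genome:
    """A genome (or assembly) as an ordered list of blocks on one contig."""

    name: str
    blocks: list[Block]

    @property
    def seq(self) -> str:
        return "".join(b.seq for b in self.blocks)

    def __len__(self) -> int:
        return sum(len(b.seq) for b in self.blocks)

    def block_spans(self) -> list[tuple[Block, int, int]]:
        out, pos = [], 0
        for b in self.blocks:
            out.append((b, pos, pos + len(b.seq)))
            pos += len(b.seq)
        return out

    def records(self) -> dict[str, str]:
        """FASTA-style view: a single record named after the genome."""
        return {self.name: self.seq}


def _draw_copies(rng: np.random.Generator, cfg: SimConfig) -> tuple[int, int]:
    lo_a, hi_a = cfg.copy_range_a
    lo_b, hi_b = cfg.copy_range_b
    if hi_a < 2 and hi_b < 2:
        raise ConfigError("CNV regions requested but both copy ranges cap at 1")
    while True:
        a = int(rng.integers(lo_a, hi_a + 1))
        b = int(rng.integers(lo_b, hi_b + 1))
        if max(a, b) >= 2:
            return a, b


def generate_genomes(
    config: SimConfig,
) -> tuple[Genome, Genome, pd.DataFrame, pd.DataFrame]:
    """Build the species pair, gene annotation and truth table.

    Returns ``(genome_a, genome_b, annotation, truth)``. The annotation
    gives species-A coordinates of the canonical (first) copy of each
    gene. The truth table records planted per-species copy numbers; its
    ``collapsed_*`` flags are filled in later by :func:`derive_assemblies`.
    """
    cfg = config
    rng = stage_rng(cfg.seed, "genomes")

    n_spacers = cfg.n_genes + 1
    spacer_len = (cfg.genome_length - cfg.n_genes * cfg.gene_length) // n_spacers
    if spacer_len < max(2 * cfg.probe_length, 100):
        raise SizingError(
            f"genome_length={cfg.genome_length} leaves spacers of {spacer_len} bp; "
            "too small to host the requested genes"
        )

    gene_ids = [f"gene{i:04d}" for i in range(cfg.n_genes)]
    gene_seqs = {g: random_dna(rng, cfg.gene_length) for g in gene_ids}
    spacers_a = [random_dna(rng, spacer_len) for _ in range(n_spacers)]

    cnv_idx = sorted(rng.choice(cfg.n_genes, size=cfg.n_cnv_regions, replace=False))
    truth_rows = []
    copies_a: dict[str, int] = {}
    copies_b: dict[str, int] = {}
    for r, gi in enumerate(cnv_idx):
        a, b = _draw_copies(rng, cfg)
        g = gene_ids[gi]
        copies_a[g], copies_b[g] = a, b
        truth_rows.append(
            {
                "region_id": f"region{r:03d}",
                "gene_id": g,
                "copies_a": a,
                "copies_b": b,
                "collapsed_a": False,
                "collapsed_b": False,
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["region_id", "gene_id", "copies_a", "copies_b", "collapsed_a", "collapsed_b"],
    )

    # species-B spacers: mutate outside the deterministic intergenic-probe
    # windows so intergenic probes stay exact in both species
    protected = _spacer_probe_windows(spacer_len, cfg)
    spacers_b = [mutate(s, cfg.divergence_rate, rng, protected) for s in spacers_a]

    def build(name: str, spacers: list[str], copies: dict[str, int]) -> Genome:
        blocks: list[Block] = [Block("spacer", spacers[0], spacer_index=0)]
        for i, g in enumerate(gene_ids):
            c = copies.get(g, 1)
            for j in range(c):
                blocks.append(Block("gene", gene_seqs[g], gene_id=g, copy_index=j))
                if j < c - 1:
                    blocks.append(
                        Block(
                            "linker",
                            random_dna(rng, cfg.copy_linker_length),
                            gene_id=g,
                            copy_index=j,
                        )
                    )
            blocks.append(Block("spacer", spacers[i + 1], spacer_index=i + 1))
        return Genome(name, blocks)

    genome_a = build(SPECIES_A, spacers_a, copies_a)
    genome_b = build(SPECIES_B, spacers_b, copies_b)

    ann_rows = []
    for b, lo, hi in genome_a.block_spans():
        if b.kind == "gene" and b.copy_index == 0:
            ann_rows.append({"gene_id": b.gene_id, "start": lo, "end": hi})
    annotation = pd.DataFrame(ann_rows, columns=["gene_id", "start", "end"])
    return genome_a, genome_b, annotation, truth


def _spacer_probe_windows(spacer_len: int, cfg: SimConfig) -> list[tuple[int, int]]:
    """Intergenic probe windows inside a spacer, one per full spacing interval."""
    n = spacer_len // cfg.intergenic_spacing
    return [
        (k * cfg.intergenic_spacing - cfg.probe_length, k * cfg.intergenic_spacing)
        for k in range(1, n + 1)
    ]


def derive_assemblies(
    genome: Genome, truth: pd.DataFrame, config: SimConfig
) -> tuple[Genome, Genome]:
    """Produce the (long-read-like, short-read-like) assembly pair.

    The long-read assembly is the genome verbatim. The short-read one
    collapses each multi-copy family with probability
    ``collapse_probability`` to its first copy only; collapse events are
    recorded in the truth table (``collapsed_a``/``collapsed_b``).
    """
    if genome.name not in (SPECIES_A, SPECIES_B):
        raise ConfigError(f"unknown species genome {genome.name!r}")
    suffix = "a" if genome.name == SPECIES_A else "b"
    rng = stage_rng(config.seed, f"collapse:{genome.name}")

    collapsed: set[str] = set()
    for row in truth.itertuples():
        copies = row.copies_a if suffix == "a" else row.copies_b
        if copies >= 2 and rng.random() < config.collapse_probability:
            collapsed.add(row.gene_id)
    truth[f"collapsed_{suffix}"] = truth["gene_id"].isin(collapsed)

    long_asm = Genome(f"{genome.name}_longread", list(genome.blocks))
    short_blocks = [
        b
        for b in genome.blocks
        if not (
            b.gene_id in collapsed
            and (b.kind == "linker" or (b.kind == "gene" and b.copy_index > 0))
        )
    ]
    short_asm = Genome(f"{genome.name}_shortread", short_blocks)
    return long_asm, short_asm


def design_probes(genome: Genome, annotation: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Design the probe set on the (species-A) reference genome.

    Three non-overlapping probes are sampled uniformly from each gene
    body; intergenic probes sit at ``intergenic_spacing`` intervals
    within each spacer. Columns: probe_id, gene_id ("" for intergenic),
    klass in {genic, intergenic}, start, end (reference coordinates),
    seq, gc.
    """
    cfg = config
    rng = stage_rng(cfg.seed, "probes")
    seq = genome.seq
    p, k = cfg.probe_length, cfg.probes_per_gene
    rows = []
    for gene in annotation.itertuples():
        L = gene.end - gene.start
        if L < k * p:
            raise ProbeDesignError(
                f"gene {gene.gene_id} ({L} bp) cannot host {k} non-overlapping {p}-mers"
            )
        # sorted draws with replacement + i*p offset => pairwise gaps >= p
        xs = np.sort(rng.integers(0, L - k * p + 1, size=k))
        offsets = xs + np.arange(k) * p
        for j, off in enumerate(offsets):
            start = gene.start + int(off)
            s = seq[start : start + p]
            rows.append(
                {
                    "probe_id": f"{gene.gene_id}_p{j}",
                    "gene_id": gene.gene_id,
                    "klass": "genic",
                    "start": start,
                    "end": start + p,
                    "seq": s,
                    "gc": gc_fraction(s),
                }
            )
    for b, lo, hi in genome.block_spans():
        if b.kind != "spacer":
            continue
        for w, (wlo, whi) in enumerate(_spacer_probe_windows(len(b.seq), cfg)):
            start = lo + wlo
            s = seq[start : start + p]
            rows.append(
                {
                    "probe_id": f"ig{b.spacer_index:04d}_{w}",
                    "gene_id": "",
                    "klass": "intergenic",
                    "start": start,
                    "end": start + p,
                    "seq": s,
                    "gc": gc_fraction(s),
                }
            )
    return pd.DataFrame(
        rows, columns=["probe_id", "gene_id", "klass", "start", "end", "seq", "gc"]
    )


def probe_truth(probeset: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-probe expected hit counts in all four assemblies plus the true ratio.

    Background probes (single-copy genes and intergenic) are 1 everywhere.
    Index: probe_id; columns a_long, a_short, b_long, b_short,
    true_log2_ratio, in_cnv_region.
    """
    by_gene = truth.set_index("gene_id")
    rows = []
    for pr in probeset.itertuples():
        if pr.gene_id and pr.gene_id in by_gene.index:
            t = by_gene.loc[pr.gene_id]
            a, b = int(t.copies_a), int(t.copies_b)
            a_s = 1 if t.collapsed_a else a
            b_s = 1 if t.collapsed_b else b
            rows.append((pr.probe_id, a, a_s, b, b_s, float(np.log2(a / b)), True))
        else:
            rows.append((pr.probe_id, 1, 1, 1, 1, 0.0, False))
    return pd.DataFrame(
        rows,
        columns=[
            "probe_id", "a_long", "a_short", "b_long", "b_short",
            "true_log2_ratio", "in_cnv_region",
        ],
    ).set_index("probe_id")


def simulate_hybridization(
    probeset: pd.DataFrame, truth: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Simulate the four two-channel arrays.

    Species A is the test channel, species B the reference. Per probe and
    array the log2 ratio is log2(a/b) + gc_bias_coeff*(GC - mean GC) +
    N(0, noise_sd); biological samples may additionally perturb test-side
    copy numbers at ``intra_species_cnv_rate`` per region, and the
    technical pair shares its biological sample's copy numbers. Channel
    intensities are brightness * 2^(±ratio/2) so log2(test/ref) recovers
    the simulated ratio.

    Returns a long table (probe_id, array_id, test_intensity,
    ref_intensity) sorted by array then probe.
    """
    cfg = config
    rng = stage_rng(cfg.seed, "arrays")
    a0 = np.ones(len(probeset))
    b0 = np.ones(len(probeset))
    region_members: dict[str, np.ndarray] = {}
    gene_col = probeset["gene_id"].to_numpy()
    for t in truth.itertuples():
        mask = gene_col == t.gene_id
        a0[mask] = t.copies_a
        b0[mask] = t.copies_b
        region_members[t.gene_id] = mask

    gc = probeset["gc"].to_numpy(dtype=float)
    gc_term = cfg.gc_bias_coeff * (gc - gc.mean())

    # per-biological-sample test-side copy numbers
    sample_copies = {}
    for sample in ("Bio1", "Bio2", "Bio3"):
        a = a0.copy()
        if cfg.intra_species_cnv_rate > 0:
            for g, mask in region_members.items():
                if rng.random() < cfg.intra_species_cnv_rate:
                    delta = 1 if rng.random() < 0.5 else -1
                    a[mask] = np.maximum(1, a[mask] + delta)
        sample_copies[sample] = a

    array_to_sample = {
        "Bio1": "Bio1",
        "Bio2": "Bio2",
        "Bio3-TechA": "Bio3",
        "Bio3-TechB": "Bio3",
    }
    frames = []
    for array_id in ARRAY_IDS:
        a = sample_copies[array_to_sample[array_id]]
        ratio = np.log2(a / b0) + gc_term
        if cfg.noise_sd > 0:
            ratio = ratio + rng.normal(0.0, cfg.noise_sd, size=len(probeset))
        brightness = 1000.0 * np.exp(rng.normal(0.0, 0.25, size=len(probeset)))
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": probeset["probe_id"].to_numpy(),
                    "array_id": array_id,
                    "test_intensity": brightness * np.exp2(ratio / 2.0),
                    "ref_intensity": brightness * np.exp2(-ratio / 2.0),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


GO_CATEGORIES = ("MF", "BP", "CC")


def generate_go_annotation(
    annotation: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimConfig,
    n_terms: int = 50,
    max_terms_per_gene: int = 4,
    enrichment_factor: float = 1.0,
    enriched_fraction: float = 0.1,
) -> tuple[pd.DataFrame, list[str]]:
    """Flat gene -> GO map with optionally enriched terms among CNV genes.

    A ``enriched_fraction`` share of the vocabulary is assigned to genes
    in CNV regions with sampling weight multiplied by
    ``enrichment_factor``, so enrichment recovery is testable. Returns
    (annotation table, list of enriched term ids).
    """
    if n_terms < 1:
        raise ConfigError("n_terms must be >= 1")
    rng = stage_rng(config.seed, "go")
    term_ids = [f"GO:{7000000 + i:07d}" for i in range(n_terms)]
    term_names = [f"synthetic process {i}" for i in range(n_terms)]
    categories = [GO_CATEGORIES[i % 3] for i in range(n_terms)]
    n_enriched = max(1, int(round(enriched_fraction * n_terms)))
    enriched = sorted(rng.choice(n_terms, size=n_enriched, replace=False))
    cnv_genes = set(truth["gene_id"])

    base = np.ones(n_terms)
    boosted = base.copy()
    boosted[list(enriched)] = enrichment_factor
    rows = []
    for gene_id in annotation["gene_id"]:
        w = boosted if gene_id in cnv_genes else base
        k = int(rng.integers(1, max_terms_per_gene + 1))
        picks = rng.choice(n_terms, size=k, replace=False, p=w / w.sum())
        for t in sorted(picks):
            rows.append(
                {
                    "gene_id": gene_id,
                    "term_id": term_ids[t],
                    "term_name": term_names[t],
                    "category": categories[t],
                }
            )
    df = pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name", "category"])
    return df, [term_ids[t] for t in enriched]


def config_to_dict(config: SimConfig) -> dict:
    return dataclasses.asdict(config)
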