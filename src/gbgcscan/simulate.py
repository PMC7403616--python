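"""Forward codon-evolution simulator with lineage-specific gBGC.

Generates the full synthetic input bundle for the detection pipeline:
per-gene codon alignments evolved on the fixed species tree under the
YN98(F3X4) model, a genome layout with spatially clustered GC-skewed
regions, a genetic map, simulated gene families, and a ground-truth
table for parameter-recovery testing.

Evolution is simulated by exact continuous-time Markov chain sampling
per codon site (event-resolved Gillespie), so the true per-branch
per-category substitution counts are available as an oracle for the
substitution-mapping estimator.  On branches belonging to the gerbil
branch set (Gerbillinae stem plus the two gerbil terminals by default),
genes inside a configured gBGC region evolve with all weak-to-strong
rates multiplied by ``ws_bias`` and the whole matrix multiplied by
``rate_multiplier`` — the latter emulating the mutagenic effect of
recombination itself, which elevates every mutational category.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import codons as cd
from . import phylo

__all__ = [
    "GbgcRegion",
    "SimulationConfig",
    "SimulatedGene",
    "Bundle",
    "default_params",
    "simulate_gene",
    "generate_bundle",
    "write_bundle",
    "neutral_config",
    "recovery_config",
]


def default_params() -> cd.YN98Params:
    """Baseline mammalian-like YN98 parameters: kappa 3 (transition bias),
    omega 0.15 (purifying selection), mildly GC-rich positional
    frequencies (GC3 of the stationary distribution about 0.53)."""
    pi = np.array(
        [
            [0.27, 0.23, 0.30, 0.20],  # position 1: A C G T
            [0.32, 0.22, 0.18, 0.28],  # position 2
            [0.22, 0.27, 0.26, 0.25],  # position 3
        ]
    )
    return cd.YN98Params(kappa=3.0, omega=0.15, pi=pi, ws_bias=1.0)


@dataclass(frozen=True)
class GbgcRegion:
    """A genomic interval whose genes experience gBGC on gerbil branches."""

    chromosome: str
    start_mb: float
    end_mb: float
    ws_bias: float
    rate_multiplier: float
    n_genes: int

    def __post_init__(self):
        if self.end_mb <= self.start_mb:
            raise ValueError("region end must exceed start")
        if self.ws_bias < 1 or self.rate_multiplier < 1:
            raise ValueError("ws_bias and rate_multiplier must be >= 1")
        if self.n_genes < 1:
            raise ValueError("region must contain at least one gene")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic bundle.

    Defaults give 200 genes on five 50-Mb chromosomes with gene lengths
    log-normal around 300 codons — a deliberately reduced genome that
    keeps the full pipeline runnable on one CPU while preserving the
    gene-density and subtelomere geometry needed by the spatial tests.
    """

    n_genes: int = 200
    n_chromosomes: int = 5
    chromosome_length_mb: float = 50.0
    gene_length_log_mean: float = 5.7   # exp(5.7) ~ 299 codons
    gene_length_log_sd: float = 0.35
    gene_length_min_codons: int = 140
    kappa: float = 3.0
    omega: float = 0.15
    pi: list = field(default_factory=lambda: default_params().pi.tolist())
    gbgc_regions: list[GbgcRegion] = field(default_factory=list)
    gerbil_branch_set: tuple[str, ...] = phylo.GERBIL_BRANCH_SET
    tree_newick: str = phylo.DEFAULT_TREE_NEWICK
    subtelomere_fraction: float = 0.10
    subtelomere_margin_mb: float = 5.0
    n_paralogs: int = 8
    paralog_divergence: float = 0.6
    map_cm_per_mb: float = 0.57
    seed: int = 0

    def params(self) -> cd.YN98Params:
        return cd.YN98Params(kappa=self.kappa, omega=self.omega,
                             pi=np.asarray(self.pi))

    def validate(self) -> None:
        chroms = {r.chromosome for r in self.gbgc_regions}
        valid = {f"chr{i + 1}" for i in range(self.n_chromosomes)}
        unknown = chroms - valid
        if unknown:
            raise ValueError(f"regions on unknown chromosomes: {sorted(unknown)}")
        for r in self.gbgc_regions:
            if r.end_mb > self.chromosome_length_mb:
                raise ValueError(f"region {r} extends past chromosome end")
        # non-overlap within chromosomes
        by_chrom: dict[str, list[GbgcRegion]] = {}
        for r in self.gbgc_regions:
            by_chrom.setdefault(r.chromosome, []).append(r)
        for regs in by_chrom.values():
            regs = sorted(regs, key=lambda r: r.start_mb)
            for a, b in zip(regs, regs[1:]):
                if b.start_mb < a.end_mb:
                    raise ValueError(f"overlapping regions {a} and {b}")
        n_region_genes = sum(r.n_genes for r in self.gbgc_regions)
        if n_region_genes > self.n_genes:
            raise ValueError("more region genes requested than genes in total")


def neutral_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Null bundle: no gBGC anywhere (ws_bias 1 on every branch)."""
    return SimulationConfig(seed=seed, gbgc_regions=[], **overrides)


def recovery_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Frozen recovery conditions: two clustered gBGC regions (14 genes in
    3 Mb each) with ws_bias 6 and a twofold overall rate elevation on the
    gerbil branches."""
    regions = [
        GbgcRegion("chr1", 10.0, 13.0, ws_bias=6.0, rate_multiplier=2.0,
                   n_genes=14),
        GbgcRegion("chr3", 30.0, 33.0, ws_bias=6.0, rate_multiplier=2.0,
                   n_genes=14),
    ]
    return SimulationConfig(seed=seed, gbgc_regions=regions, **overrides)


@dataclass
class SimulatedGene:
    """One simulated alignment plus its event-resolved truth."""

    alignment: dict[str, str]
    #: true substitution counts per branch (keyed by child-node name) in
    #: the eight-category order of :data:`gbgcscan.codons.CATEGORY_LABELS`.
    branch_counts: dict[str, np.ndarray]

    def total_counts(self) -> np.ndarray:
        return np.sum(list(self.branch_counts.values()), axis=0)


def _jump_tables(q: np.ndarray):
    rates = -np.diag(q)
    probs = q / rates[:, None]
    np.fill_diagonal(probs, 0.0)
    return rates, np.cumsum(probs, axis=1)


def _evolve_branch(states, rates, cum_probs, t, rng, cat_counts=None):
    """Evolve all sites along one branch of length t in place (Gillespie,
    vectorized over sites)."""
    cat = cd.category_matrix()
    remaining = np.full(states.shape, float(t))
    alive = np.nonzero(remaining > 0)[0] if t > 0 else np.empty(0, dtype=int)
    while alive.size:
        lam = rates[states[alive]]
        w = rng.exponential(1.0, size=alive.size) / lam
        remaining[alive] -= w
        jump = remaining[alive] > 0
        jidx = alive[jump]
        if jidx.size:
            old = states[jidx].copy()
            u = rng.random(jidx.size)
            new = (cum_probs[old] < u[:, None]).sum(axis=1)
            states[jidx] = new
            if cat_counts is not None:
                np.add.at(cat_counts, cat[old, new], 1)
        alive = jidx
    return states


def simulate_gene(
    tree: phylo.TreeIndex,
    params: cd.YN98Params,
    length: int,
    gerbil_override: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
    gerbil_branch_set: tuple[str, ...] = phylo.GERBIL_BRANCH_SET,
    record_truth: bool = True,
) -> SimulatedGene:
    """Simulate one gene of ``length`` codons along the tree.

    The root sequence is drawn from the stationary distribution of the
    baseline (unbiased) matrix; each branch is evolved by event-resolved
    CTMC sampling.  ``gerbil_override = (ws_bias, rate_multiplier)``, if
    given, replaces the matrix on branches in ``gerbil_branch_set``.
    """
    if length < 1:
        raise ValueError("gene length must be at least one codon")
    if tree.n_tips == 0:
        raise ValueError("tree has no tips")
    rng = rng if rng is not None else np.random.default_rng()

    base_params = replace(params, ws_bias=1.0)
    q0 = cd.build_rate_matrix(base_params)
    freqs = cd.codon_frequencies(base_params.pi)
    tables0 = _jump_tables(q0)
    tables_biased = None
    if gerbil_override is not None:
        ws_bias, rate_mult = gerbil_override
        qb = cd.build_rate_matrix(replace(params, ws_bias=ws_bias)) * rate_mult
        tables_biased = _jump_tables(qb)

    states = {tree.root: rng.choice(len(cd.SENSE_CODONS), size=length, p=freqs)}
    branch_counts: dict[str, np.ndarray] = {}
    for v in tree.preorder():
        if v == tree.root:
            continue
        name = tree.names[v]
        biased = tables_biased is not None and name in gerbil_branch_set
        rates, cum_probs = tables_biased if biased else tables0
        s = states[tree.parent[v]].copy()
        counts = np.zeros(8, dtype=float) if record_truth else None
        _evolve_branch(s, rates, cum_probs, tree.edge_length[v], rng, counts)
        states[v] = s
        if record_truth:
            branch_counts[name] = counts

    alignment = {
        name: "".join(cd.SENSE_CODONS[i] for i in states[v])
        for name, v in tree.tip_index.items()
    }
    return SimulatedGene(alignment=alignment, branch_counts=branch_counts)


@dataclass
class Bundle:
    """In-memory synthetic input bundle with ground truth."""

    config: SimulationConfig
    tree_newick: str
    alignments: dict[str, dict[str, str]]
    layout: pd.DataFrame          # gene, chromosome, start, end (bp, 0-based half-open)
    chromosome_lengths: dict[str, int]
    genetic_map: pd.DataFrame     # gene, linkage_group, cM
    families: pd.DataFrame        # family, gene, n_comparators
    family_sequences: dict[str, dict[str, str]]   # family -> {seq_id: sequence}
    truth: pd.DataFrame           # gene, is_gbgc_gene, region, ws_bias, rate_multiplier


def _sample_gene_lengths(cfg: SimulationConfig, rng) -> np.ndarray:
    raw = rng.lognormal(cfg.gene_length_log_mean, cfg.gene_length_log_sd,
                        size=cfg.n_genes)
    return np.maximum(raw.astype(int), cfg.gene_length_min_codons)


def _place_genes(cfg: SimulationConfig, lengths_bp, rng) -> pd.DataFrame:
    """Assign genomic midpoints: region genes evenly spaced inside their
    region (a dense cluster), a configured fraction of the remaining genes
    inside the 5-Mb terminal windows, the rest uniform outside regions."""
    chrom_len = int(cfg.chromosome_length_mb * 1e6)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    records: list[tuple[str, float, str, float, float]] = []

    gene_ids = [f"gene{i + 1:04d}" for i in range(cfg.n_genes)]
    order = list(range(cfg.n_genes))
    i = 0
    for ridx, region in enumerate(cfg.gbgc_regions):
        width = region.end_mb - region.start_mb
        for k in range(region.n_genes):
            mid_mb = region.start_mb + (k + 0.5) * width / region.n_genes
            records.append((region.chromosome, mid_mb * 1e6,
                            f"region{ridx + 1}", region.ws_bias,
                            region.rate_multiplier))
            i += 1
    n_free = cfg.n_genes - i
    n_sub = int(round(cfg.subtelomere_fraction * n_free))
    margin = cfg.subtelomere_margin_mb * 1e6

    def in_region(chrom, pos_bp):
        for r in cfg.gbgc_regions:
            if r.chromosome == chrom and r.start_mb * 1e6 <= pos_bp < r.end_mb * 1e6:
                return True
        return False

    for _ in range(n_sub):
        while True:
            chrom = chroms[rng.integers(cfg.n_chromosomes)]
            if rng.random() < 0.5:
                pos = rng.uniform(0, margin)
            else:
                pos = rng.uniform(chrom_len - margin, chrom_len)
            if not in_region(chrom, pos):
                break
        records.append((chrom, pos, "", 1.0, 1.0))
    for _ in range(n_free - n_sub):
        while True:
            chrom = chroms[rng.integers(cfg.n_chromosomes)]
            pos = rng.uniform(0, chrom_len)
            if not in_region(chrom, pos):
                break
        records.append((chrom, pos, "", 1.0, 1.0))

    rows = []
    for gid, idx in zip(gene_ids, order):
        chrom, mid, region, ws, rm = records[idx]
        half = lengths_bp[idx] / 2
        start = int(max(0, min(mid - half, chrom_len - lengths_bp[idx])))
        end = int(start + lengths_bp[idx])
        rows.append((gid, chrom, start, end, region, ws, rm))
    return pd.DataFrame(
        rows,
        columns=["gene", "chromosome", "start", "end", "region",
                 "ws_bias", "rate_multiplier"],
    )


def generate_bundle(config: SimulationConfig) -> Bundle:
    """Generate the complete synthetic bundle deterministically from the
    config seed: alignments, genome layout, genetic map, gene families
    with simulated paralogs, and ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    params = config.params()
    tree = phylo.index_tree(phylo.read_tree(config.tree_newick))

    lengths_codons = _sample_gene_lengths(config, rng)
    placed = _place_genes(config, lengths_codons * 3, rng)

    alignments: dict[str, dict[str, str]] = {}
    family_rows = []
    family_sequences: dict[str, dict[str, str]] = {}
    q0 = cd.build_rate_matrix(replace(params, ws_bias=1.0))
    tables0 = _jump_tables(q0)
    freqs = cd.codon_frequencies(params.pi)

    for i, row in placed.iterrows():
        gid = row.gene
        override = None
        if row.region:
            override = (row.ws_bias, row.rate_multiplier)
        gene = simulate_gene(
            tree, params, int(lengths_codons[i]),
            gerbil_override=override, rng=rng,
            gerbil_branch_set=config.gerbil_branch_set,
            record_truth=False,
        )
        alignments[gid] = gene.alignment
        # paralog comparators: independent neutral lineages from a fresh
        # stationary ancestor of the same length
        fam = f"fam_{gid}"
        seqs = {}
        for p in range(config.n_paralogs):
            anc = rng.choice(len(cd.SENSE_CODONS), size=int(lengths_codons[i]),
                             p=freqs)
            _evolve_branch(anc, *tables0, config.paralog_divergence, rng)
            seqs[f"{fam}_paralog{p + 1}"] = "".join(
                cd.SENSE_CODONS[k] for k in anc
            )
        family_sequences[fam] = seqs
        family_rows.append((fam, gid, config.n_paralogs))

    chrom_lengths = {
        f"chr{i + 1}": int(config.chromosome_length_mb * 1e6)
        for i in range(config.n_chromosomes)
    }
    layout = placed[["gene", "chromosome", "start", "end"]].copy()
    mid_mb = (placed.start + placed.end) / 2 / 1e6
    genetic_map = pd.DataFrame(
        {
            "gene": placed.gene,
            "linkage_group": placed.chromosome,
            "cM": (mid_mb * config.map_cm_per_mb).round(6),
        }
    )
    truth = pd.DataFrame(
        {
            "gene": placed.gene,
            "is_gbgc_gene": placed.region != "",
            "region": placed.region,
            "ws_bias": placed.ws_bias,
            "rate_multiplier": placed.rate_multiplier,
        }
    )
    families = pd.DataFrame(family_rows,
                            columns=["family", "gene", "n_comparators"])
    return Bundle(
        config=config,
        tree_newick=config.tree_newick,
        alignments=alignments,
        layout=layout,
        chromosome_lengths=chrom_lengths,
        genetic_map=genetic_map,
        families=families,
        family_sequences=family_sequences,
        truth=truth,
    )


def write_bundle(bundle: Bundle, outdir: str | Path) -> Path:
    """Persist a bundle as plain-text files (FASTA / Newick / BED / TSV /
    JSON) under ``outdir``."""
    out = Path(outdir)
    (out / "alignments").mkdir(parents=True, exist_ok=True)
    for gid, aln in bundle.alignments.items():
        with open(out / "alignments" / f"{gid}.fasta", "w") as fh:
            for sp, seq in sorted(aln.items()):
                fh.write(f">{sp}\n{seq}\n")
    (out / "tree.nwk").write_text(bundle.tree_newick + "\n")
    with open(out / "genes.bed", "w") as fh:
        for r in bundle.layout.itertuples(index=False):
            fh.write(f"{r.chromosome}\t{r.start}\t{r.end}\t{r.gene}\n")
    with open(out / "chromosomes.tsv", "w") as fh:
        fh.write("chromosome\tlength\n")
        for c, ln in bundle.chromosome_lengths.items():
            fh.write(f"{c}\t{ln}\n")
    bundle.genetic_map.to_csv(out / "genetic_map.tsv", sep="\t", index=False)
    bundle.families.to_csv(out / "families.tsv", sep="\t", index=False)
    with open(out / "families.fasta", "w") as fh:
        for fam in sorted(bundle.family_sequences):
            for sid, seq in sorted(bundle.family_sequences[fam].items()):
                fh.write(f">{sid}\n{seq}\n")
    truth = bundle.truth.to_dict(orient="records")
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    cfg = asdict(bundle.config)
    cfg["gbgc_regions"] = [asdict(r) for r in bundle.config.gbgc_regions]
    (out / "config.json").write_text(json.dumps(cfg, indent=1, default=str))
    return out
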