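"""Synthetic MeDIP-chip cohort generator with planted ground truth.

Emulates a two-channel (bound/input) promoter tiling-array study: a small
cohort split into a case and a control group, triplicate arrays per
individual, promoters tiled from 1000 bp upstream to 250 bp downstream of
the TSS at 100 bp spacing.  Differential methylation is planted on the log2
scale, uniformly across a promoter's probes, with a configurable fraction of
hypermethylated (case > control) effects, spatial clustering of planted
promoters in dense genomic blocks, and miRNA/target consistency structure.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: probe offsets relative to the TSS, in transcription direction (bp)
OFFSETS = np.arange(-1000, 201, 100)
#: number of probes tiled per promoter
PROBES_PER_PROMOTER = len(OFFSETS)  # 13
#: probe length in bp
PROBE_LENGTH = 50

BASES = np.array(list("ACGT"))


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is invalid."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the emulated study: 12 case vs 28 control individuals,
    3 replicate arrays each, ~31% of planted effects hypermethylated, with
    miRNA promoters interleaved among gene promoters.
    """

    n_case: int = 12
    n_control: int = 28
    n_replicates: int = 3
    n_promoters: int = 2000
    n_mirnas: int = 50
    fraction_dm: float = 0.05
    fraction_hyper: float = 0.31
    effect_size: float = 0.5
    individual_sd: float = 0.25
    replicate_sd: float = 0.25
    dye_bias_amplitude: float = 0.0
    seed: int = 0
    # genome layout
    n_chromosomes: int = 2
    chromosome_length: int = 50_000_000
    n_cluster_blocks: int = 2
    block_width: int = 750_000
    block_promoters: int = 20
    # planted miRNA structure
    n_dm_mirnas: int = 8
    mirna_fraction_hyper: float = 0.79
    # baseline methylation / intensity model
    baseline_mean: float = 0.3
    baseline_sd: float = 0.4
    probe_jitter_sd: float = 0.1
    input_log2_mean: float = 11.0
    input_log2_sd: float = 0.8
    # promoter-sequence CpG observed/expected targets
    cpg_oe_background: float = 0.42
    cpg_oe_hypo: float = 0.86
    cpg_oe_hyper: float = 0.38

    def validate(self) -> None:
        counts = {
            "n_case": self.n_case,
            "n_control": self.n_control,
            "n_replicates": self.n_replicates,
            "n_promoters": self.n_promoters,
            "n_chromosomes": self.n_chromosomes,
            "chromosome_length": self.chromosome_length,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive, got {value}")
        for name in ("fraction_dm", "fraction_hyper", "mirna_fraction_hyper"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value}")
        if self.n_mirnas < 0 or self.n_mirnas > self.n_promoters:
            raise ConfigurationError("n_mirnas must lie in [0, n_promoters]")
        for name in ("individual_sd", "replicate_sd", "probe_jitter_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    @property
    def n_individuals(self) -> int:
        return self.n_case + self.n_control

    @property
    def n_arrays(self) -> int:
        return self.n_individuals * self.n_replicates


@dataclass
class GenomeLayout:
    """Promoter/probe geometry of the synthetic genome.

    ``promoters`` columns: promoter_id, gene_id, chromosome, tss, strand,
    cls (``gene``/``miRNA``), block (dense-block index, -1 outside blocks).
    ``probes`` columns: probe_id, promoter_id, chromosome, start, end,
    offset, gene_id, cls, strand.  Coordinates are 0-based half-open.
    """

    chromosomes: list[tuple[str, int]]
    promoters: pd.DataFrame
    probes: pd.DataFrame
    dense_blocks: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chromosome", "start", "end"])
    )

    @property
    def n_promoters(self) -> int:
        return len(self.promoters)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def promoter_codes(self) -> np.ndarray:
        """Integer promoter index per probe, aligned with ``promoters`` rows."""
        cat = pd.Categorical(
            self.probes["promoter_id"], categories=self.promoters["promoter_id"]
        )
        return np.asarray(cat.codes)


@dataclass
class SyntheticTruth:
    """Planted ground truth: which promoters are differential and how."""

    dm_effects: pd.Series  # promoter_id -> signed log2 effect
    dm_mirnas: list[str]
    cluster_blocks: pd.DataFrame  # chromosome, start, end, direction
    mirna_target_map: dict[str, set[str]] = field(default_factory=dict)
    consistent_mirnas: list[str] = field(default_factory=list)

    def direction(self, promoter_id: str) -> str:
        return "hyper" if self.dm_effects.loc[promoter_id] > 0 else "hypo"


def generate_genome_layout(config: SimulationConfig) -> GenomeLayout:
    """Lay out promoters and probes on the synthetic genome.

    Each promoter receives 13 probes at offsets -1000..+200 (step 100 bp)
    relative to its TSS.  A few dense blocks of promoters are placed on a
    250 kb grid so that spatial-clustering statistics have structure to find.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chromosomes = [(name, config.chromosome_length) for name in chrom_names]

    n_block = min(
        config.n_cluster_blocks * config.block_promoters, config.n_promoters
    )
    n_background = config.n_promoters - n_block

    # dense blocks, aligned to a 250 kb grid, round-robin across chromosomes
    grid = 250_000
    block_rows = []
    block_tss: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    if n_block:
        remaining = n_block
        per_block = []
        for _ in range(config.n_cluster_blocks):
            size = min(config.block_promoters, remaining)
            per_block.append(size)
            remaining -= size
        for b, size in enumerate(per_block):
            if size <= 0:
                continue
            chrom = chrom_names[b % config.n_chromosomes]
            n_slots = config.chromosome_length // grid - config.block_width // grid - 8
            start = int((4 + rng.integers(0, max(n_slots, 1))) * grid)
            end = start + config.block_width
            pad = config.block_width // 20
            tss = np.linspace(start + pad, end - pad, size)
            tss = (tss + rng.integers(-pad // 2, pad // 2 + 1, size)).astype(int)
            block_rows.append((chrom, start, end))
            block_tss[chrom].extend((int(t), b) for t in tss)
    dense_blocks = pd.DataFrame(block_rows, columns=["chromosome", "start", "end"])

    # background promoters: uniform over the chromosome interior
    per_chrom = np.full(config.n_chromosomes, n_background // config.n_chromosomes)
    per_chrom[: n_background % config.n_chromosomes] += 1
    margin = 1_100  # keep probes on-chromosome
    records = []
    for chrom, n_bg in zip(chrom_names, per_chrom):
        lattice = np.arange(margin, config.chromosome_length - margin, 1000)
        pos = rng.choice(lattice, size=n_bg, replace=False)
        entries = [(int(p), -1) for p in pos] + block_tss[chrom]
        entries.sort()
        # enforce strictly increasing TSS
        tss_arr = np.array([t for t, _ in entries])
        while True:
            dup = np.flatnonzero(np.diff(tss_arr) <= 0)
            if dup.size == 0:
                break
            tss_arr[dup + 1] = tss_arr[dup] + 1
        for (_, blk), t in zip(entries, tss_arr):
            records.append((chrom, int(t), blk))

    promoters = pd.DataFrame(records, columns=["chromosome", "tss", "block"])
    promoters = promoters.sort_values(["chromosome", "tss"], kind="stable")
    promoters = promoters.reset_index(drop=True)
    n = len(promoters)
    promoters["promoter_id"] = [f"P{i:05d}" for i in range(n)]
    promoters["strand"] = np.where(rng.random(n) < 0.5, "+", "-")

    mirna_idx = np.sort(rng.choice(n, size=config.n_mirnas, replace=False))
    cls = np.full(n, "gene", dtype=object)
    cls[mirna_idx] = "miRNA"
    promoters["cls"] = cls
    gene_ids = np.empty(n, dtype=object)
    g = m = 0
    for i in range(n):
        if cls[i] == "miRNA":
            gene_ids[i] = f"MIR{m:04d}"
            m += 1
        else:
            gene_ids[i] = f"GENE{g:05d}"
            g += 1
    promoters["gene_id"] = gene_ids
    promoters = promoters[
        ["promoter_id", "gene_id", "chromosome", "tss", "strand", "cls", "block"]
    ]

    # probes: 13 per promoter, strand-aware genomic placement
    rep = np.repeat(np.arange(n), PROBES_PER_PROMOTER)
    offs = np.tile(OFFSETS, n)
    tss = promoters["tss"].to_numpy()[rep]
    plus = (promoters["strand"].to_numpy() == "+")[rep]
    start = np.where(plus, tss + offs, tss - offs - PROBE_LENGTH)
    probes = pd.DataFrame(
        {
            "probe_id": [
                f"{pid}_{k:02d}"
                for pid in promoters["promoter_id"]
                for k in range(PROBES_PER_PROMOTER)
            ],
            "promoter_id": promoters["promoter_id"].to_numpy()[rep],
            "chromosome": promoters["chromosome"].to_numpy()[rep],
            "start": start.astype(int),
            "end": start.astype(int) + PROBE_LENGTH,
            "offset": offs,
            "gene_id": promoters["gene_id"].to_numpy()[rep],
            "cls": promoters["cls"].to_numpy()[rep],
            "strand": promoters["strand"].to_numpy()[rep],
        }
    )
    return GenomeLayout(chromosomes, promoters, probes, dense_blocks)


def simulate_truth(layout: GenomeLayout, config: SimulationConfig) -> SyntheticTruth:
    """Plant differential promoters: dense blocks, miRNAs, then random fill.

    Each dense block is single-direction (hyper with probability
    ``fraction_hyper``); planted miRNAs are hypermethylated with probability
    ``mirna_fraction_hyper``; the remaining planted gene promoters get iid
    signs.  Effect magnitude is ``effect_size`` log2 units throughout.
    """
    rng = np.random.default_rng(config.seed + 1)
    n_dm = int(round(config.fraction_dm * layout.n_promoters))
    prom = layout.promoters
    effects: dict[str, float] = {}
    block_rows = []

    if n_dm > 0:
        for b in sorted(set(prom["block"]) - {-1}):
            members = prom.loc[prom["block"] == b]
            if len(effects) + len(members) > n_dm:
                members = members.iloc[: max(n_dm - len(effects), 0)]
            if members.empty:
                continue
            sign = 1.0 if rng.random() < config.fraction_hyper else -1.0
            for pid in members["promoter_id"]:
                effects[pid] = sign * config.effect_size
            block_rows.append(
                (
                    members["chromosome"].iloc[0],
                    int(prom.loc[prom["block"] == b, "tss"].min()) - 1000,
                    int(prom.loc[prom["block"] == b, "tss"].max()) + 1250,
                    "hyper" if sign > 0 else "hypo",
                )
            )

    mirna_prom = prom.loc[(prom["cls"] == "miRNA") & (~prom["promoter_id"].isin(effects))]
    n_dm_mirnas = min(config.n_dm_mirnas, len(mirna_prom), max(n_dm - len(effects), 0))
    dm_mirnas: list[str] = []
    if n_dm_mirnas > 0:
        chosen = rng.choice(mirna_prom.index.to_numpy(), size=n_dm_mirnas, replace=False)
        for idx in np.sort(chosen):
            pid = prom.at[idx, "promoter_id"]
            sign = 1.0 if rng.random() < config.mirna_fraction_hyper else -1.0
            effects[pid] = sign * config.effect_size
            dm_mirnas.append(pid)

    remaining = prom.loc[~prom["promoter_id"].isin(effects), "promoter_id"].to_numpy()
    n_fill = n_dm - len(effects)
    if n_fill > 0:
        chosen = rng.choice(remaining, size=n_fill, replace=False)
        signs = np.where(rng.random(n_fill) < config.fraction_hyper, 1.0, -1.0)
        for pid, s in zip(chosen, signs):
            effects[pid] = s * config.effect_size

    dm = pd.Series(effects, name="delta", dtype=float)
    dm = dm.reindex(prom.loc[prom["promoter_id"].isin(dm.index), "promoter_id"])
    blocks = pd.DataFrame(
        block_rows, columns=["chromosome", "start", "end", "direction"]
    )
    return SyntheticTruth(dm_effects=dm, dm_mirnas=dm_mirnas, cluster_blocks=blocks)


def simulate_arrays(
    layout: GenomeLayout, truth: SyntheticTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate two-channel intensities for every array.

    Returns ``(bound, input, sample_sheet)``: bound/input are probes x arrays
    DataFrames of Cy5/Cy3 intensities; the sample sheet has one row per array
    with individual, replicate, group and two socio-economic covariates.

    Model, per probe and array::

        input  ~ 2^{Normal(input_log2_mean, input_log2_sd)}
        bound  = input * 2^{m + delta*case + individual + replicate + bias(A)}

    where ``m`` is the probe's baseline methylation level (promoter-level
    draw plus per-probe jitter), ``delta`` the planted effect for probes of
    differential promoters, ``individual`` an individual-level biological
    deviation (per probe, shared across that individual's replicates) and
    ``replicate`` technical noise.  The dye bias is a linear trend in the
    standardized average log intensity A, with configurable amplitude
    (default 0).
    """
    config.validate()
    missing = set(truth.dm_effects.index) - set(layout.promoters["promoter_id"])
    if missing:
        raise ValueError(f"truth promoters absent from layout: {sorted(missing)[:5]}")
    rng = np.random.default_rng(config.seed + 2)
    n_probes = layout.n_probes
    n_ind = config.n_individuals
    n_arrays = config.n_arrays

    codes = layout.promoter_codes()
    m_prom = rng.normal(config.baseline_mean, config.baseline_sd, layout.n_promoters)
    m = m_prom[codes] + rng.normal(0.0, config.probe_jitter_sd, n_probes)

    delta = np.zeros(layout.n_promoters)
    idx = layout.promoters.set_index("promoter_id").index
    delta[idx.get_indexer(truth.dm_effects.index)] = truth.dm_effects.to_numpy()
    delta_probe = delta[codes]

    individuals = [f"I{i:02d}" for i in range(n_ind)]
    groups = np.array(["case"] * config.n_case + ["control"] * config.n_control)
    case = groups == "case"
    sep = rng.choice(["low", "high"], size=(n_ind, 2))

    # biological (individual-level) deviation: per probe, per individual
    eps = rng.normal(0.0, config.individual_sd, size=(n_probes, n_ind))

    sheet_rows = []
    bound_cols = {}
    input_cols = {}
    for i, ind in enumerate(individuals):
        y_ind = m + delta_probe * case[i] + eps[:, i]
        for r in range(config.n_replicates):
            array_id = f"{ind}_r{r + 1}"
            log2_input = rng.normal(
                config.input_log2_mean, config.input_log2_sd, n_probes
            )
            log2_ratio = y_ind + rng.normal(0.0, config.replicate_sd, n_probes)
            log2_bound = log2_input + log2_ratio
            if config.dye_bias_amplitude:
                a = log2_bound + log2_input
                z = (a - a.mean()) / a.std()
                log2_bound = log2_bound + config.dye_bias_amplitude * z
            bound_cols[array_id] = np.exp2(log2_bound)
            input_cols[array_id] = np.exp2(log2_input)
            sheet_rows.append(
                (array_id, ind, r + 1, groups[i], sep[i, 0], sep[i, 1])
            )

    probe_index = pd.Index(layout.probes["probe_id"], name="probe_id")
    bound = pd.DataFrame(bound_cols, index=probe_index)
    input_ = pd.DataFrame(input_cols, index=probe_index)
    sheet = pd.DataFrame(
        sheet_rows,
        columns=["array_id", "individual_id", "replicate", "group", "child_SEP", "adult_SEP"],
    )
    assert len(sheet) == n_arrays
    return bound, input_, sheet


def generate_target_map(
    layout: GenomeLayout,
    truth: SyntheticTruth,
    config: SimulationConfig,
    n_targets: int = 50,
    enrichment_odds: float = 5.0,
    n_consistent: int = 4,
    planted_counts: dict[str, tuple[int, int]] | None = None,
) -> dict[str, set[str]]:
    """Assign target-gene sets to every miRNA promoter.

    The first ``n_consistent`` hypermethylated planted miRNAs receive target
    sets sampled with ``enrichment_odds``-fold weight on hypomethylated
    planted genes; all other miRNAs draw targets uniformly.  With odds 1 the
    planted consistency vanishes.  ``planted_counts`` forces exact
    (n_targets, n_hypo) compositions for specific miRNA promoter ids.
    Updates ``truth.mirna_target_map``/``truth.consistent_mirnas`` in place
    and returns the map keyed by miRNA gene id.
    """
    prom = layout.promoters
    mirnas = prom.loc[prom["cls"] == "miRNA"]
    if mirnas.empty:
        raise ValueError("layout contains no miRNA promoters")
    genes = prom.loc[prom["cls"] == "gene", ["promoter_id", "gene_id"]]
    gene_ids = genes["gene_id"].to_numpy()
    if n_targets > len(gene_ids):
        raise ValueError(
            f"requested target-set size {n_targets} exceeds gene count {len(gene_ids)}"
        )
    rng = np.random.default_rng(config.seed + 3)

    hypo_ids = set(
        prom.loc[
            prom["promoter_id"].isin(
                truth.dm_effects.index[truth.dm_effects < 0]
            )
            & (prom["cls"] == "gene"),
            "gene_id",
        ]
    )
    is_hypo = np.isin(gene_ids, list(hypo_ids))

    hyper_dm_mirnas = [
        pid for pid in truth.dm_mirnas if truth.dm_effects.loc[pid] > 0
    ]
    consistent = hyper_dm_mirnas[:n_consistent] if enrichment_odds != 1.0 else []
    pid_to_gene = dict(zip(prom["promoter_id"], prom["gene_id"]))

    target_map: dict[str, set[str]] = {}
    for pid, mid in zip(mirnas["promoter_id"], mirnas["gene_id"]):
        if planted_counts and pid in planted_counts:
            nt, nh = planted_counts[pid]
            if nh > is_hypo.sum() or nt - nh > (~is_hypo).sum():
                raise ValueError("planted counts exceed available genes")
            chosen = np.concatenate(
                [
                    rng.choice(gene_ids[is_hypo], size=nh, replace=False),
                    rng.choice(gene_ids[~is_hypo], size=nt - nh, replace=False),
                ]
            )
        elif pid in consistent:
            w = np.where(is_hypo, enrichment_odds, 1.0)
            chosen = rng.choice(
                gene_ids, size=n_targets, replace=False, p=w / w.sum()
            )
        else:
            chosen = rng.choice(gene_ids, size=n_targets, replace=False)
        target_map[mid] = set(chosen)

    truth.mirna_target_map = target_map
    truth.consistent_mirnas = [pid_to_gene[p] for p in consistent]
    return target_map


def simulate_promoter_sequences(
    layout: GenomeLayout, truth: SyntheticTruth, config: SimulationConfig
) -> dict[str, str]:
    """Generate a promoter-region sequence per promoter (length 1250 bp).

    Sequences are drawn from a first-order Markov chain whose C->G transition
    probability is tuned so the expected normalized CpG frequency
    (observed/expected) matches the configured class target: hypomethylated
    planted promoters are CpG-rich, hypermethylated ones CpG-poor, and the
    background sits in between.
    """
    rng = np.random.default_rng(config.seed + 4)
    length = int(OFFSETS[-1] - OFFSETS[0] + PROBE_LENGTH)  # 1250 bp window

    def transition(oe: float) -> np.ndarray:
        # Keep P(C|any)=0.25 so the stationary C frequency stays 0.25, and
        # solve the C->G probability so the stationary CpG observed/expected
        # ratio p_cg / pi_G equals the target:
        # pi_G = 0.25*p_cg + 0.75*0.25  =>  p_cg = 0.1875*oe / (1 - 0.25*oe)
        t = np.full((4, 4), 0.25)
        p_cg = 0.1875 * oe / (1.0 - 0.25 * oe)
        rest = (0.75 - p_cg) / 2.0
        t[1] = [rest, 0.25, p_cg, rest]
        return t

    classes = {}
    for pid in layout.promoters["promoter_id"]:
        if pid in truth.dm_effects.index:
            oe = (
                config.cpg_oe_hypo
                if truth.dm_effects.loc[pid] < 0
                else config.cpg_oe_hyper
            )
        else:
            oe = config.cpg_oe_background
        classes.setdefault(oe, []).append(pid)

    sequences: dict[str, str] = {}
    for oe, pids in classes.items():
        n = len(pids)
        cum = transition(oe).cumsum(axis=1)
        states = np.empty((n, length), dtype=np.int8)
        states[:, 0] = rng.integers(0, 4, n)
        u = rng.random((n, length))
        for t in range(1, length):
            states[:, t] = (u[:, t, None] > cum[states[:, t - 1]]).sum(axis=1)
        for i, pid in enumerate(pids):
            sequences[pid] = "".join(BASES[states[i]])
    return {pid: sequences[pid] for pid in layout.promoters["promoter_id"]}


def generate_gene_sets(
    layout: GenomeLayout,
    truth: SyntheticTruth,
    config: SimulationConfig,
    n_sets: int = 20,
    planted_fraction: float = 0.5,
) -> dict[str, set[str]]:
    """Random gene sets plus two sets enriched for planted hypo/hyper genes."""
    rng = np.random.default_rng(config.seed + 5)
    genes = layout.promoters.loc[layout.promoters["cls"] == "gene", "gene_id"]
    genes = genes.to_numpy()
    pid_dir = {
        pid: ("hyper" if d > 0 else "hypo") for pid, d in truth.dm_effects.items()
    }
    dm_genes = {
        d: layout.promoters.loc[
            layout.promoters["promoter_id"].map(pid_dir.get) == d, "gene_id"
        ].to_numpy()
        for d in ("hypo", "hyper")
    }
    sets: dict[str, set[str]] = {}
    for i in range(n_sets):
        size = min(int(rng.integers(30, 200)), genes.size)
        sets[f"SET{i:03d}"] = set(rng.choice(genes, size=size, replace=False))
    for d in ("hypo", "hyper"):
        pool = dm_genes[d]
        if pool.size == 0:
            continue
        n_dm = max(int(planted_fraction * min(40, pool.size)), 1)
        members = set(rng.choice(pool, size=n_dm, replace=False))
        members |= set(rng.choice(genes, size=min(80, genes.size), replace=False))
        sets[f"PLANTED_{d.upper()}"] = members
    return sets
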