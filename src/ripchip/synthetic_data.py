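"""Seeded generator of spot-level two-channel RIP-chip experiments.

The generator emulates the statistical structure of ribonucleoprotein-IP
hybridisations against a total-RNA reference, with known ground truth, so
that every pipeline stage is testable offline:

* per-gene mRNA abundances are log-normal; the reference channel measures
  abundance times multiplicative spot noise;
* the IP channel measures a small constant carryover fraction of each
  mRNA's abundance (non-specific background, rescaled by scanner gain),
  times an enrichment effect for the bait's own mRNA, its targets and the
  planted contaminants, times spot noise;
* pixel-quality fractions follow a logistic link from the spot's expected
  log10 signal, so dim spots fail the platform QC rules exactly as on real
  scans; the fractions carry no extra per-spot jitter, which keeps spot
  dropout all-or-none within a gene and per-gene measurement precision
  homogeneous (a generator contract: spurious genes must enter a
  k-replicate consensus at a rate consistent with the per-replicate tail
  raised to the k);
* effect sizes are specified in SD units of the resulting enrichment
  profile, not raw multipliers: the generator calibrates a per-gene signal
  boost so the gene's median log-ratio lands at (median + effect·SD) of the
  post-QC background distribution, making tests robust to noise settings;
* condition semantics: a −ATG mutation removes only the designated mRNA's
  enrichment while leaving its reference-channel abundance unchanged;
  puromycin and EDTA disassemble polysomes and remove all
  translation-dependent enrichments (bait and targets) while non-ribosomal
  sticky contaminants persist.

A fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .array_io import (
    ArrayScan,
    Blacklist,
    GeneAnnotation,
    SpotRecord,
    get_platform,
    write_annotation,
    write_blacklist,
    write_spot_table,
)
from .errors import ConfigError

_TRANSLATION_INDEPENDENT = frozenset({"puromycin", "edta"})


@dataclass
class SyntheticConfig:
    """Study conditions for one simulated RIP-chip experiment series.

    Defaults: 5,000 coding genes (the order of the fission-yeast coding
    set), 3 probes per gene (array designs carry a platform-determined
    probe multiplicity between 2 and 5; pass a ``(lo, hi)`` tuple for a
    per-gene range), log-normal abundances (log10 mean 2.0, SD 0.6), 1%
    IP carryover rescaled by a scanner gain of 100 so both channels use
    the same dynamic range, multiplicative per-channel spot noise of
    0.1 log10 units, bait self-enrichment 6 SD, two targets at 5 and 3 SD,
    two contaminants at 4 SD, and k = 3 biological replicates with the
    last replicate dye-swapped.
    """

    n_genes: int = 5000
    probes_per_gene: int | tuple[int, int] = 3
    n_noncoding: int = 50
    abundance_log10_mean: float = 2.0
    abundance_log10_sd: float = 0.6
    carryover: float = 0.01
    ip_gain: float = 100.0
    spot_noise_log10_sd: float = 0.1
    bait_gene: str | None = None
    bait_self_effect_sd: float = 6.0
    target_effects: Mapping[str, float] | Sequence[float] = (5.0, 3.0)
    contaminant_effects: Mapping[str, float] | Sequence[float] = (4.0, 4.0)
    pixel_midpoint: float = 0.8
    pixel_slope: float = 4.0
    k: int = 3
    dye_swap_replicates: tuple[int, ...] | None = None  # default: last replicate
    condition: str = "control"
    minus_atg_gene: str | None = None  # default: strongest target
    minus_atg_abundance_factor: float = 1.0
    platform: str = "pcr"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ConfigError("n_genes must be >= 2")
        if not 0.0 < self.carryover <= 1.0:
            raise ConfigError("carryover must be in (0, 1]")
        if self.spot_noise_log10_sd < 0 or self.abundance_log10_sd < 0:
            raise ConfigError("noise SDs must be non-negative")
        if self.condition not in {"control", "minus_atg", "puromycin", "edta", "mock"}:
            raise ConfigError(f"unknown condition {self.condition!r}")
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if isinstance(self.probes_per_gene, (tuple, list)):
            lo, hi = self.probes_per_gene
            if not 1 <= lo <= hi:
                raise ConfigError(f"bad probes_per_gene range {self.probes_per_gene}")
            self.probes_per_gene = (int(lo), int(hi))
        elif self.probes_per_gene < 1:
            raise ConfigError("probes_per_gene must be >= 1")
        get_platform(self.platform)
        if self.minus_atg_abundance_factor <= 0:
            raise ConfigError("minus_atg_abundance_factor must be positive")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks."""

    bait_gene: str
    target_effects: dict[str, float]
    contaminant_effects: dict[str, float]
    condition: str
    minus_atg_gene: str | None
    expected_enriched: frozenset[str]
    abundance: dict[str, float]
    annotation: tuple[GeneAnnotation, ...]
    seed: int

    def expected_consensus(self, apply_blacklist: bool = True) -> frozenset[str]:
        """Genes the pipeline should call, optionally after subtracting the
        planted contaminants (the blacklist the pipeline would use)."""
        out = set(self.expected_enriched)
        if apply_blacklist:
            out -= set(self.contaminant_effects)
        return frozenset(out)

    @property
    def blacklist(self) -> Blacklist:
        return Blacklist(frozenset(self.contaminant_effects))


@dataclass
class _Design:
    gene_ids: list[str]
    abundance: np.ndarray  # per coding gene, linear scale
    spot_gene: np.ndarray  # per coding spot: gene index
    probe_ids: list[str]  # per coding spot
    nc_gene_ids: list[str]
    nc_abundance: np.ndarray
    nc_probe_ids: list[str]
    annotation: tuple[GeneAnnotation, ...]
    bait_gene: str
    target_effects: dict[str, float]
    contaminant_effects: dict[str, float]
    gene_index: dict[str, int]


def _design_rng(config: SyntheticConfig) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))


def _replicate_rng(config: SyntheticConfig, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), 1 + rep]))


def _as_effect_dict(
    effects: Mapping[str, float] | Sequence[float],
    pick_gene,
    label: str,
) -> dict[str, float]:
    if isinstance(effects, Mapping):
        return {str(g): float(d) for g, d in effects.items()}
    return {pick_gene(label, j): float(d) for j, d in enumerate(effects)}


def _build_design(config: SyntheticConfig) -> _Design:
    rng = _design_rng(config)
    n = config.n_genes
    gene_ids = [f"g{i + 1:04d}" for i in range(n)]
    abundance = 10.0 ** rng.normal(
        config.abundance_log10_mean, config.abundance_log10_sd, n
    )
    if isinstance(config.probes_per_gene, tuple):
        lo, hi = config.probes_per_gene
        probes_per_gene = rng.integers(lo, hi + 1, n)
    else:
        probes_per_gene = np.full(n, int(config.probes_per_gene))
    spot_gene = np.repeat(np.arange(n), probes_per_gene)
    probe_counter = np.concatenate([np.arange(c) for c in probes_per_gene])
    probe_ids = [
        f"{gene_ids[g]}.p{j + 1}" for g, j in zip(spot_gene, probe_counter)
    ]

    nc_gene_ids = [f"nc{i + 1:03d}" for i in range(config.n_noncoding)]
    nc_abundance = 10.0 ** rng.normal(
        config.abundance_log10_mean, config.abundance_log10_sd, config.n_noncoding
    )
    nc_probe_ids = [f"{g}.p1" for g in nc_gene_ids]

    annotation = tuple(
        [
            GeneAnnotation(pid, gene_ids[g], True)
            for pid, g in zip(probe_ids, spot_gene)
        ]
        + [GeneAnnotation(pid, g, False) for pid, g in zip(nc_probe_ids, nc_gene_ids)]
    )

    # spiked genes default to comfortably expressed messages (an IP can only
    # recover mRNAs the cell expresses at detectable levels): walk down the
    # abundance ranking from the 80th percentile in 2%-quantile steps
    order = np.argsort(abundance)
    used: set[str] = set()
    slots = iter(range(200))

    def pick_gene(label: str, j: int) -> str:
        for slot in slots:
            q = 0.80 - 0.02 * slot
            if q <= 0.05:
                raise ConfigError("too many spiked genes for auto-assignment")
            gene = gene_ids[order[int(round(q * (n - 1)))]]
            if gene not in used:
                used.add(gene)
                return gene
        raise ConfigError("auto-assignment exhausted")

    bait = config.bait_gene or pick_gene("bait", 0)
    used.add(bait)
    targets = _as_effect_dict(config.target_effects, pick_gene, "target")
    used.update(targets)
    contaminants = _as_effect_dict(config.contaminant_effects, pick_gene, "contaminant")

    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for g in (bait, *targets, *contaminants):
        if g not in gene_index:
            raise ConfigError(f"spiked gene {g!r} not in the array design")
    for label, d in {**targets, **contaminants, bait: config.bait_self_effect_sd}.items():
        if d < 0:
            raise ConfigError(f"effect for {label!r} must be >= 0, got {d}")

    return _Design(
        gene_ids=gene_ids,
        abundance=abundance,
        spot_gene=spot_gene,
        probe_ids=probe_ids,
        nc_gene_ids=nc_gene_ids,
        nc_abundance=nc_abundance,
        nc_probe_ids=nc_probe_ids,
        annotation=annotation,
        bait_gene=bait,
        target_effects=targets,
        contaminant_effects=contaminants,
        gene_index=gene_index,
    )


def design_annotation(config: SyntheticConfig) -> tuple[GeneAnnotation, ...]:
    """The probe annotation of the design a config generates (deterministic)."""
    return _build_design(config).annotation


def _active_effects(config: SyntheticConfig, design: _Design) -> dict[str, float]:
    """Per-condition enrichment effects (gene -> SD units)."""
    if config.condition in _TRANSLATION_INDEPENDENT:
        # polysome disassembly abolishes all cotranslational enrichments;
        # sticky contaminants bind outside the ribosome and persist
        return dict(design.contaminant_effects)
    effects = dict(design.contaminant_effects)
    effects.update(design.target_effects)
    if config.bait_self_effect_sd > 0:
        effects[design.bait_gene] = config.bait_self_effect_sd
    if config.condition == "minus_atg":
        gene = config.minus_atg_gene or _default_minus_atg_gene(design)
        if gene not in effects:
            raise ConfigError(
                f"minus_atg gene {gene!r} is not a spiked bait/target mRNA"
            )
        del effects[gene]
    return {g: d for g, d in effects.items() if d > 0}


def _default_minus_atg_gene(design: _Design) -> str:
    if not design.target_effects:
        raise ConfigError("minus_atg condition needs at least one target")
    return max(design.target_effects, key=design.target_effects.get)


def _simulate_scan(
    config: SyntheticConfig,
    design: _Design,
    effects: dict[str, float],
    rep: int,
) -> ArrayScan:
    rng = _replicate_rng(config, rep)
    platform = get_platform(config.platform)
    nsd = config.spot_noise_log10_sd
    mid, slope = config.pixel_midpoint, config.pixel_slope

    abund = design.abundance.copy()
    if config.condition == "minus_atg" and config.minus_atg_abundance_factor != 1.0:
        gene = config.minus_atg_gene or _default_minus_atg_gene(design)
        abund[design.gene_index[gene]] *= config.minus_atg_abundance_factor

    log_ab_spot = np.log10(abund)[design.spot_gene]
    n_spots = log_ab_spot.size
    # one draw per channel per spot; draw order is condition-independent so a
    # fixed seed pairs conditions spot-for-spot
    log_ref = log_ab_spot + rng.normal(0.0, nsd, n_spots) if nsd > 0 else log_ab_spot.copy()
    ip_offset = np.log10(config.carryover * config.ip_gain)
    log_ip0 = (
        log_ab_spot + ip_offset + (rng.normal(0.0, nsd, n_spots) if nsd > 0 else 0.0)
    )
    nc_noise = rng.normal(0.0, nsd, (2, len(design.nc_gene_ids))) if nsd > 0 else np.zeros(
        (2, len(design.nc_gene_ids))
    )

    # calibrate per-gene IP boosts so each spiked gene's post-QC median
    # log-ratio lands at (median + effect_sd * SD) of the profile the
    # pipeline will compute; R is linear in the boost, so a couple of
    # fixed-point iterations converge once the QC mask stabilises
    spiked = {g: 0.0 for g in effects}
    spot_idx = {
        g: np.flatnonzero(design.spot_gene == design.gene_index[g]) for g in effects
    }
    # pixel-quality fractions come from the expected (noise-free) log signal:
    # spots of one gene then pass or fail QC together, so surviving genes are
    # always measured with their full probe complement
    log_ip_expected0 = log_ab_spot + ip_offset
    f_ref = expit(slope * (log_ab_spot - mid))
    L0 = log_ip0 - log_ref
    for _ in range(3 if spiked else 1):
        delta_spot = np.zeros(n_spots)
        for g, dlt in spiked.items():
            delta_spot[spot_idx[g]] = dlt
        log_ip = log_ip0 + delta_spot
        f_ip = expit(slope * (log_ip_expected0 + delta_spot - mid))
        qc = ((f_ip >= platform.min_frac_ip) & (f_ref >= platform.min_frac_ref)) | (
            f_ip >= platform.min_frac_ip_alone
        )
        if not spiked:
            break
        L = L0 + delta_spot
        surv = pd.Series(L[qc]).groupby(design.spot_gene[qc]).median()
        if len(surv) < 2:
            break
        med = float(np.median(surv.values))
        sd = float(np.std(surv.values, ddof=1))
        if sd <= 0.0:
            break
        for g, d in effects.items():
            gi = design.gene_index[g]
            r_g = float(surv.get(gi, np.median(L[spot_idx[g]])))
            spiked[g] += (med + d * sd) - r_g

    ip = 10.0 ** log_ip
    ref = 10.0 ** log_ref
    nc_log_ab = np.log10(design.nc_abundance)
    nc_log_ref = nc_log_ab + nc_noise[0]
    nc_log_ip = nc_log_ab + ip_offset + nc_noise[1]
    nc_f_ref = expit(slope * (nc_log_ab - mid))
    nc_f_ip = expit(slope * (nc_log_ab + ip_offset - mid))

    swap_set = (
        set(config.dye_swap_replicates)
        if config.dye_swap_replicates is not None
        else {config.k - 1}
    )
    swapped = rep in {r % config.k for r in swap_set}

    def spot(pid, ip_v, ref_v, fi, fr):
        if swapped:
            ip_v, ref_v, fi, fr = ref_v, ip_v, fr, fi
        return SpotRecord(pid, float(ip_v), float(ref_v), float(fi), float(fr), flag=0)

    spots = [
        spot(pid, ip[i], ref[i], f_ip[i], f_ref[i])
        for i, pid in enumerate(design.probe_ids)
    ] + [
        spot(pid, 10.0 ** nc_log_ip[i], 10.0 ** nc_log_ref[i], nc_f_ip[i], nc_f_ref[i])
        for i, pid in enumerate(design.nc_probe_ids)
    ]
    return ArrayScan(
        experiment_id=f"{design.bait_gene}-{config.condition}-r{rep + 1}",
        bait_gene=design.bait_gene,
        platform=platform.name,
        dye_swapped=swapped,
        condition=config.condition,
        spots=tuple(spots),
    )


def simulate_experiment(config: SyntheticConfig) -> tuple[list[ArrayScan], GroundTruth]:
    """Generate k replicate scans plus the ground truth that produced them."""
    design = _build_design(config)
    effects = _active_effects(config, design)
    scans = [_simulate_scan(config, design, effects, rep) for rep in range(config.k)]
    minus_atg_gene = (
        (config.minus_atg_gene or _default_minus_atg_gene(design))
        if config.condition == "minus_atg"
        else config.minus_atg_gene
    )
    truth = GroundTruth(
        bait_gene=design.bait_gene,
        target_effects=design.target_effects,
        contaminant_effects=design.contaminant_effects,
        condition=config.condition,
        minus_atg_gene=minus_atg_gene,
        expected_enriched=frozenset(effects),
        abundance=dict(zip(design.gene_ids, design.abundance.tolist())),
        annotation=design.annotation,
        seed=config.seed,
    )
    return scans, truth


def simulate_null(config: SyntheticConfig) -> list[ArrayScan]:
    """Scans with no planted enrichment at all (calibration harness)."""
    design = _build_design(config)
    return [_simulate_scan(config, design, {}, rep) for rep in range(config.k)]


def write_simulation(
    scans: Sequence[ArrayScan],
    truth: GroundTruth,
    config: SyntheticConfig,
    outdir: str | Path,
) -> None:
    """Write scans, manifest, annotation, blacklist, ground truth and config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("file\texperiment_id\tbait_gene\tplatform\tdye_swapped\tcondition\n")
        for i, scan in enumerate(scans):
            fname = f"scan_r{i + 1}.tsv"
            write_spot_table(scan, outdir / fname)
            fh.write(
                f"{fname}\t{scan.experiment_id}\t{scan.bait_gene}\t{scan.platform}\t"
                f"{int(scan.dye_swapped)}\t{scan.condition}\n"
            )
    write_annotation(truth.annotation, outdir / "annotation.tsv")
    write_blacklist(truth.blacklist, outdir / "blacklist.txt")
    with open(outdir / "ground_truth.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\trole\teffect_sd\tactive\n")
        fh.write(
            f"{truth.bait_gene}\tbait\t-\t{int(truth.bait_gene in truth.expected_enriched)}\n"
        )
        for g, d in sorted(truth.target_effects.items()):
            fh.write(f"{g}\ttarget\t{d:.6g}\t{int(g in truth.expected_enriched)}\n")
        for g, d in sorted(truth.contaminant_effects.items()):
            fh.write(f"{g}\tcontaminant\t{d:.6g}\t{int(g in truth.expected_enriched)}\n")
    cfg = dataclasses.asdict(config)
    for key, val in cfg.items():
        if isinstance(val, tuple):
            cfg[key] = list(val)
        elif isinstance(val, Mapping):
            cfg[key] = dict(val)
    with open(outdir / "config.yaml", "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
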