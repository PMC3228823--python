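"""Composition helpers: scan file → QC → mapping → standardised profile → calls."""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Mapping, Sequence

from .array_io import (
    ArrayScan,
    Blacklist,
    GeneAnnotation,
    PlatformSpec,
    get_platform,
    map_probes_to_genes,
    resolve_dye_swap,
)
from .enrichment import (
    DEFAULT_MIN_BACKGROUND,
    StandardizedProfile,
    gene_log_ratios,
    standardize,
)
from .spot_qc import QCResult, filter_scan
from .target_calling import CallParameters, CallSet, build_callset


def scan_to_standardized(
    scan: ArrayScan,
    annotation: Iterable[GeneAnnotation] | Mapping[str, GeneAnnotation],
    platform: PlatformSpec | str | None = None,
    min_background: int = DEFAULT_MIN_BACKGROUND,
) -> tuple[StandardizedProfile, QCResult]:
    """One scan through the full per-experiment pipeline.

    Dye-swap orientation is resolved first, then spot QC, probe-to-gene
    mapping (coding probes only), median log-ratios and standardisation.
    """
    resolved = resolve_dye_swap(scan)
    qc = filter_scan(resolved, platform if platform is not None else resolved.platform)
    kept_scan = replace(resolved, spots=tuple(qc.kept))
    mapping = map_probes_to_genes(kept_scan, annotation)
    profile = gene_log_ratios(
        mapping.spots_by_gene, dye_swapped=False, experiment_id=scan.experiment_id
    )
    return standardize(profile, min_background=min_background), qc


def call_bait(
    scans: Sequence[ArrayScan],
    annotation: Iterable[GeneAnnotation] | Mapping[str, GeneAnnotation],
    params: CallParameters | None = None,
    blacklist: Blacklist | None = None,
    platform: PlatformSpec | str | None = None,
    min_background: int = DEFAULT_MIN_BACKGROUND,
) -> CallSet:
    """Replicate scans for one bait → consensus call set."""
    if not scans:
        raise ValueError("no input scans")
    baits = {s.bait_gene for s in scans}
    if len(baits) != 1:
        raise ValueError(f"scans mix baits: {sorted(baits)}")
    profiles = [
        scan_to_standardized(s, annotation, platform, min_background)[0] for s in scans
    ]
    return build_callset(profiles, baits.pop(), params, blacklist)
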