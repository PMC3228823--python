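"""Condition comparisons: −ATG, puromycin and EDTA perturbation reports.

Each (bait, mRNA, condition, replicate) cell carries either the numeric
SD-above-median score s, the code ``P`` (mRNA clearly present in the IP but
the background distribution could not be computed) or ``ND`` (mRNA not
detectable in the IP).  A condition pair receives a verdict: ``lost`` when
the mRNA is enriched in every baseline replicate and in no treated
replicate, ``retained`` when it is enriched throughout, else
``inconclusive``.  ND counts as below threshold (an undetectable mRNA cannot
be enriched); P cells are resolved only when the verdict is the same whether
P is read as above or below threshold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .array_io import (
    ArrayScan,
    GeneAnnotation,
    PlatformSpec,
    _annotation_index,
    get_platform,
    map_probes_to_genes,
    resolve_dye_swap,
)
from .enrichment import DEFAULT_MIN_BACKGROUND, gene_log_ratios, standardize
from .errors import BackgroundTooSmallError, DegenerateProfileError, GeneNotOnArrayError
from .spot_qc import filter_scan, is_ip_detectable

CODE_P = "P"
CODE_ND = "ND"

VERDICT_LOST = "lost"
VERDICT_RETAINED = "retained"
VERDICT_INCONCLUSIVE = "inconclusive"

Score = float | str


@dataclass(frozen=True)
class ReportCell:
    bait: str
    mrna: str
    condition: str
    replicate: int
    value: Score


@dataclass(frozen=True)
class VerdictRow:
    bait: str
    mrna: str
    baseline: str
    treated: str
    verdict: str


@dataclass
class PerturbationReport:
    cells: list[ReportCell]
    verdicts: list[VerdictRow]


def score_or_code(
    gene: str,
    scan: ArrayScan,
    annotation: Iterable[GeneAnnotation] | Mapping[str, GeneAnnotation],
    platform: PlatformSpec | str | None = None,
    min_background: int = DEFAULT_MIN_BACKGROUND,
) -> Score:
    """Numeric s score for ``gene`` in ``scan``, or the code P or ND.

    Raises :class:`GeneNotOnArrayError` when the gene has no probes on the
    design — a missing probe is not the same as an undetectable mRNA.
    """
    resolved = resolve_dye_swap(scan)
    platform = get_platform(platform if platform is not None else resolved.platform)
    index = _annotation_index(annotation)
    gene_probes = {p for p, a in index.items() if a.gene_id == gene and a.is_coding}
    gene_spots = [s for s in resolved.spots if s.probe_id in gene_probes]
    if not gene_spots:
        raise GeneNotOnArrayError(gene)

    detectable = any(
        is_ip_detectable(s, platform) for s in gene_spots if s.flag >= 0
    )
    if not detectable:
        return CODE_ND

    qc = filter_scan(resolved, platform)
    from dataclasses import replace as _replace

    mapping = map_probes_to_genes(_replace(resolved, spots=tuple(qc.kept)), index)
    profile = gene_log_ratios(
        mapping.spots_by_gene, dye_swapped=False, experiment_id=scan.experiment_id
    )
    try:
        std = standardize(profile, min_background=min_background)
    except (BackgroundTooSmallError, DegenerateProfileError):
        # mRNA is present but the background distribution is not computable
        return CODE_P
    if gene not in std.s:
        # detectable spots imply positive signals, so this is unreachable in
        # practice; treat defensively as present-without-background
        return CODE_P
    return std.s[gene]


def _verdict_numeric(control: Sequence[float], treated: Sequence[float], tau: float) -> str:
    all_control_above = all(v >= tau for v in control)
    if all_control_above and not any(v >= tau for v in treated):
        return VERDICT_LOST
    if all_control_above and all(v >= tau for v in treated):
        return VERDICT_RETAINED
    return VERDICT_INCONCLUSIVE


def compare_conditions(
    control_scores: Sequence[Score],
    treated_scores: Sequence[Score],
    tau: float = 2.0,
) -> str:
    """Verdict for one mRNA across a baseline arm and a treated arm."""
    if not control_scores or not treated_scores:
        raise ValueError("both arms need at least one replicate")

    def substitute(values: Sequence[Score], p_assignment: Iterable[float]):
        it = iter(p_assignment)
        out = []
        for v in values:
            if v == CODE_ND:
                out.append(float("-inf"))
            elif v == CODE_P:
                out.append(next(it))
            else:
                out.append(float(v))
        return out

    n_p = sum(v == CODE_P for v in (*control_scores, *treated_scores))
    if n_p > 12:  # unrealistic arm sizes; resolve conservatively
        return VERDICT_INCONCLUSIVE
    verdicts = set()
    for assignment in itertools.product((float("inf"), float("-inf")), repeat=n_p):
        it = iter(assignment)
        nc = sum(v == CODE_P for v in control_scores)
        c = substitute(control_scores, assignment[:nc])
        t = substitute(treated_scores, assignment[nc:])
        verdicts.add(_verdict_numeric(c, t, tau))
        if len(verdicts) > 1:
            return VERDICT_INCONCLUSIVE
    return verdicts.pop()


@dataclass(frozen=True)
class RawSignalPair:
    probe_id: str
    plus_atg_ref: float
    minus_atg_ref: float


def compare_raw_expression(
    plus_atg_scan: ArrayScan,
    minus_atg_scan: ArrayScan,
    gene: str,
    annotation: Iterable[GeneAnnotation] | Mapping[str, GeneAnnotation],
) -> list[RawSignalPair]:
    """Paired raw reference-channel signals for one gene's probes.

    No QC, no normalisation: this is the raw-expression sanity check that the
    untranslatable (−ATG) mRNA is still expressed at wild-type-like levels.
    Channel orientation is resolved (metadata), nothing else is touched.
    """
    index = _annotation_index(annotation)
    gene_probes = {p for p, a in index.items() if a.gene_id == gene}
    if not gene_probes:
        raise GeneNotOnArrayError(gene)

    pairs: list[RawSignalPair] = []
    for name, scan in (("plus_atg", plus_atg_scan), ("minus_atg", minus_atg_scan)):
        resolved = resolve_dye_swap(scan)
        by_probe: dict[str, list[float]] = {}
        for s in resolved.spots:
            if s.probe_id in gene_probes:
                by_probe.setdefault(s.probe_id, []).append(s.ref_signal)
        if not by_probe:
            raise GeneNotOnArrayError(f"{gene} absent from the {name} array design")
        if name == "plus_atg":
            plus_by_probe = by_probe
        else:
            minus_by_probe = by_probe
    for probe in sorted(set(plus_by_probe) & set(minus_by_probe)):
        for a, b in zip(plus_by_probe[probe], minus_by_probe[probe]):
            pairs.append(RawSignalPair(probe, a, b))
    if not pairs:
        raise GeneNotOnArrayError(f"{gene}: no probes shared between the two designs")
    return pairs


def build_report(
    bait: str,
    genes: Sequence[str],
    baseline_scans: Sequence[ArrayScan],
    treated_scans: Sequence[ArrayScan],
    annotation: Iterable[GeneAnnotation] | Mapping[str, GeneAnnotation],
    platform: PlatformSpec | str | None = None,
    tau: float = 2.0,
    min_background: int = DEFAULT_MIN_BACKGROUND,
) -> PerturbationReport:
    """Score each mRNA in both arms and attach a lost/retained verdict."""
    if not baseline_scans or not treated_scans:
        raise ValueError("both arms need at least one scan")
    index = _annotation_index(annotation)
    cells: list[ReportCell] = []
    verdicts: list[VerdictRow] = []
    baseline_cond = baseline_scans[0].condition
    treated_cond = treated_scans[0].condition
    for gene in genes:
        arm_scores: dict[str, list[Score]] = {"baseline": [], "treated": []}
        for arm, scans in (("baseline", baseline_scans), ("treated", treated_scans)):
            for i, scan in enumerate(scans, start=1):
                value = score_or_code(gene, scan, index, platform, min_background)
                cells.append(ReportCell(bait, gene, scan.condition, i, value))
                arm_scores[arm].append(value)
        verdicts.append(
            VerdictRow(
                bait,
                gene,
                baseline_cond,
                treated_cond,
                compare_conditions(arm_scores["baseline"], arm_scores["treated"], tau),
            )
        )
    return PerturbationReport(cells, verdicts)
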