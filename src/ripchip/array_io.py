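"""Readers, writers and probe-to-gene resolution for the pipeline's file formats.

All formats are simple tab-separated dialects with named columns (see the
package docs): a quantified spot table per hybridisation (one row per spot,
two channels: immunoprecipitate and total-RNA reference), a probe annotation
table with a coding-sequence flag, a plain-text contaminant blacklist, and
TSV outputs for call sets and perturbation reports.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

#: Closed vocabulary of experimental conditions.
CONDITIONS = frozenset({"control", "minus_atg", "puromycin", "edta", "mock"})

SPOT_TABLE_COLUMNS = (
    "probe_id",
    "ip_signal",
    "ref_signal",
    "ip_frac_above_bg",
    "ref_frac_above_bg",
    "flag",
)
_OPTIONAL_COLUMNS = ("block", "row", "col")


@dataclass(frozen=True)
class SpotRecord:
    """One quantified microarray spot.

    ``ip_frac_above_bg`` / ``ref_frac_above_bg`` are the fractions of
    foreground pixels exceeding the median local background plus two
    background standard deviations, as exported per channel by the scanner
    software.  ``flag`` < 0 marks a scanner-flagged bad spot.
    """

    probe_id: str
    ip_signal: float
    ref_signal: float
    ip_frac_above_bg: float
    ref_frac_above_bg: float
    flag: int = 0
    block: int | None = None
    row: int | None = None
    col: int | None = None

    def __post_init__(self) -> None:
        for name in ("ip_frac_above_bg", "ref_frac_above_bg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FormatError(f"{name}={v!r} outside [0, 1] for probe {self.probe_id}")
        for name in ("ip_signal", "ref_signal"):
            v = getattr(self, name)
            if v < 0:
                raise FormatError(f"{name}={v!r} negative for probe {self.probe_id}")


@dataclass(frozen=True)
class ArrayScan:
    """One hybridised array: metadata plus the ordered spot list.

    ``probe_id`` values need not be unique (arrays carry replicate spots per
    probe).  When ``dye_swapped`` is true the stored channel columns hold the
    physically swapped dyes; :func:`resolve_dye_swap` exchanges the channel
    roles before any downstream ratio is formed.
    """

    experiment_id: str
    bait_gene: str
    platform: str
    dye_swapped: bool
    condition: str
    spots: tuple[SpotRecord, ...]

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise FormatError(
                f"condition {self.condition!r} not in {sorted(CONDITIONS)}"
            )
        object.__setattr__(self, "spots", tuple(self.spots))


@dataclass(frozen=True)
class PlatformSpec:
    """Per-platform spot-quality thresholds.

    A spot passes when both channels clear (``min_frac_ip``, ``min_frac_ref``)
    or when the IP channel alone clears the stricter ``min_frac_ip_alone``.
    """

    name: str
    min_frac_ip: float
    min_frac_ref: float
    min_frac_ip_alone: float

    def __post_init__(self) -> None:
        for name in ("min_frac_ip", "min_frac_ref", "min_frac_ip_alone"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FormatError(f"{name}={v!r} outside [0, 1]")
        if self.min_frac_ip > self.min_frac_ip_alone:
            raise FormatError(
                "min_frac_ip must not exceed min_frac_ip_alone "
                f"({self.min_frac_ip} > {self.min_frac_ip_alone})"
            )


#: Built-in platforms: PCR-spotted arrays (55% IP / 90% reference, or 90% in
#: the IP channel alone) and oligonucleotide arrays (70% / 98% / 98%).
PLATFORMS: Mapping[str, PlatformSpec] = {
    "pcr": PlatformSpec("pcr", 0.55, 0.90, 0.90),
    "agilent": PlatformSpec("agilent", 0.70, 0.98, 0.98),
}


def get_platform(platform: str | PlatformSpec) -> PlatformSpec:
    """Resolve a platform name or spec to a :class:`PlatformSpec`."""
    if isinstance(platform, PlatformSpec):
        return platform
    try:
        return PLATFORMS[platform]
    except KeyError:
        raise FormatError(
            f"unknown platform {platform!r}; known: {sorted(PLATFORMS)}"
        ) from None


@dataclass(frozen=True)
class GeneAnnotation:
    probe_id: str
    gene_id: str
    is_coding: bool


@dataclass(frozen=True)
class Blacklist:
    """Set of gene IDs enriched non-specifically across unrelated baits."""

    gene_ids: frozenset[str] = frozenset()

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids

    def __len__(self) -> int:
        return len(self.gene_ids)


def read_spot_table(
    path: str | Path,
    *,
    experiment_id: str,
    bait_gene: str,
    platform: str = "pcr",
    dye_swapped: bool = False,
    condition: str = "control",
) -> ArrayScan:
    """Parse a spot table TSV into an :class:`ArrayScan`.

    Metadata (bait, dye orientation, condition) is declared by the caller,
    never guessed from the file.  Row order is preserved.  Errors name the
    offending column or data line.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SPOT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise FormatError(f"{path}: empty table (header only)")

    numeric: dict[str, pd.Series] = {}
    int_cols = ["flag"] + [c for c in _OPTIONAL_COLUMNS if c in df.columns]
    for col in ("ip_signal", "ref_signal", "ip_frac_above_bg", "ref_frac_above_bg", *int_cols):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            idx = int(bad.idxmax())
            # +2: header is line 1, data starts at line 2
            raise FormatError(
                f"{path}: non-numeric value {df[col].iloc[idx]!r} in column "
                f"{col!r} at line {idx + 2}"
            )
        numeric[col] = vals

    spots = []
    for i in range(len(df)):
        spots.append(
            SpotRecord(
                probe_id=str(df["probe_id"].iloc[i]),
                ip_signal=float(numeric["ip_signal"].iloc[i]),
                ref_signal=float(numeric["ref_signal"].iloc[i]),
                ip_frac_above_bg=float(numeric["ip_frac_above_bg"].iloc[i]),
                ref_frac_above_bg=float(numeric["ref_frac_above_bg"].iloc[i]),
                flag=int(numeric["flag"].iloc[i]),
                **{
                    c: int(numeric[c].iloc[i])
                    for c in _OPTIONAL_COLUMNS
                    if c in numeric
                },
            )
        )
    return ArrayScan(
        experiment_id=experiment_id,
        bait_gene=bait_gene,
        platform=get_platform(platform).name,
        dye_swapped=dye_swapped,
        condition=condition,
        spots=tuple(spots),
    )


def write_spot_table(scan: ArrayScan, path: str | Path) -> None:
    """Write a scan's spots back to the TSV dialect (bit-stable)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(SPOT_TABLE_COLUMNS) + "\n")
        for s in scan.spots:
            fh.write(
                f"{s.probe_id}\t{s.ip_signal:.6g}\t{s.ref_signal:.6g}\t"
                f"{s.ip_frac_above_bg:.6g}\t{s.ref_frac_above_bg:.6g}\t{s.flag}\n"
            )


def resolve_dye_swap(scan: ArrayScan) -> ArrayScan:
    """Return a scan with channel roles resolved to IP/reference.

    For dye-swapped hybridisations the stored channel columns are exchanged
    (signals and pixel fractions alike); the result always has
    ``dye_swapped=False`` and channels in their semantic roles.
    """
    if not scan.dye_swapped:
        return scan
    swapped = tuple(
        replace(
            s,
            ip_signal=s.ref_signal,
            ref_signal=s.ip_signal,
            ip_frac_above_bg=s.ref_frac_above_bg,
            ref_frac_above_bg=s.ip_frac_above_bg,
        )
        for s in scan.spots
    )
    return replace(scan, spots=swapped, dye_swapped=False)


def read_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read the probe annotation TSV (`probe_id`, `gene_id`, `is_coding`)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("probe_id", "gene_id", "is_coding"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column(s): {col}")
    return [
        GeneAnnotation(
            probe_id=str(r.probe_id),
            gene_id=str(r.gene_id),
            is_coding=str(r.is_coding).strip() not in ("0", "false", "False"),
        )
        for r in df.itertuples()
    ]


def write_annotation(annotation: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("probe_id\tgene_id\tis_coding\n")
        for a in annotation:
            fh.write(f"{a.probe_id}\t{a.gene_id}\t{int(a.is_coding)}\n")


@dataclass
class ProbeMapping:
    """Result of resolving spots to genes: coding spots only, with exclusion counts."""

    spots_by_gene: dict[str, list[SpotRecord]]
    n_noncoding: int = 0
    n_unmapped: int = 0

    @property
    def n_excluded(self) -> int:
        return self.n_noncoding + self.n_unmapped


def _annotation_index(
    annotation: Iterable[GeneAnnotation] | Mapping[str, GeneAnnotation],
) -> dict[str, GeneAnnotation]:
    if isinstance(annotation, Mapping):
        return dict(annotation)
    index: dict[str, GeneAnnotation] = {}
    for a in annotation:
        prev = index.get(a.probe_id)
        if prev is not None and prev.gene_id != a.gene_id:
            raise FormatError(
                f"probe {a.probe_id!r} annotated to two genes: "
                f"{prev.gene_id!r} and {a.gene_id!r}"
            )
        index[a.probe_id] = a
    return index


def map_probes_to_genes(
    scan: ArrayScan,
    annotation: Iterable[GeneAnnotation] | Mapping[str, GeneAnnotation],
) -> ProbeMapping:
    """Group a scan's spots by gene, keeping coding probes only.

    Probes annotated as non-coding and probes absent from the annotation are
    excluded and counted.  Only probes corresponding to coding sequences take
    part in enrichment analysis.
    """
    index = _annotation_index(annotation)
    by_gene: dict[str, list[SpotRecord]] = {}
    n_noncoding = n_unmapped = 0
    for spot in scan.spots:
        ann = index.get(spot.probe_id)
        if ann is None:
            n_unmapped += 1
        elif not ann.is_coding:
            n_noncoding += 1
        else:
            by_gene.setdefault(ann.gene_id, []).append(spot)
    if not by_gene:
        logger.warning(
            "scan %s: no coding probes mapped (%d non-coding, %d unmapped)",
            scan.experiment_id, n_noncoding, n_unmapped,
        )
    return ProbeMapping(by_gene, n_noncoding=n_noncoding, n_unmapped=n_unmapped)


def read_blacklist(path: str | Path) -> Blacklist:
    """Read a contaminant blacklist: one gene ID per line, ``#`` comments."""
    path = Path(path)
    genes: set[str] = set()
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise FormatError(f"cannot read blacklist {path}: {exc}") from exc
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.add(line)
    return Blacklist(frozenset(genes))


def write_blacklist(blacklist: Blacklist, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in sorted(blacklist.gene_ids):
            fh.write(g + "\n")


# -- CallSet persistence ------------------------------------------------------

CALLSET_COLUMNS = ("bait", "gene_id", "replicate_support", "mean_s", "is_bait_mrna", "category")


def write_callset(callset, path: str | Path) -> None:
    """Write a :class:`~ripchip.target_calling.CallSet` to its TSV schema.

    Metadata (bait, category, replicate count, expected false-positive
    fraction) goes into ``#``-prefixed header lines so a round trip through
    :func:`read_callset` restores the full summary.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# ripchip callset v1\n")
        fh.write(f"# bait={callset.bait_gene}\n")
        fh.write(f"# category={callset.category}\n")
        fh.write(f"# k={callset.k}\n")
        fh.write(f"# fp_expected={callset.fp_expected!r}\n")
        fh.write("\t".join(CALLSET_COLUMNS) + "\n")
        for gene in sorted(callset.consensus):
            n_sup, k = callset.support.get(gene, (callset.k, callset.k))
            mean_s = callset.mean_s.get(gene, float("nan"))
            fh.write(
                f"{callset.bait_gene}\t{gene}\t{n_sup}/{k}\t{mean_s:.6g}\t"
                f"{int(gene == callset.bait_gene)}\t{callset.category}\n"
            )


def read_callset(path: str | Path):
    """Read a call-set TSV written by :func:`write_callset`."""
    from .target_calling import CallSet  # local import to avoid a cycle

    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    header: list[str] | None = None
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
            continue
        if header is None:
            header = line.split("\t")
            if header != list(CALLSET_COLUMNS):
                raise FormatError(f"{path}: unexpected call-set header {header}")
            continue
        rows.append(line.split("\t"))
    if header is None:
        raise FormatError(f"{path}: no call-set header found")
    for key in ("bait", "category", "k", "fp_expected"):
        if key not in meta:
            raise FormatError(f"{path}: missing call-set metadata {key!r}")

    k = int(meta["k"])
    consensus: set[str] = set()
    support: dict[str, tuple[int, int]] = {}
    mean_s: dict[str, float] = {}
    for r in rows:
        gene = r[1]
        consensus.add(gene)
        n_sup, k_row = r[2].split("/")
        support[gene] = (int(n_sup), int(k_row))
        mean_s[gene] = float(r[3])
    return CallSet(
        bait_gene=meta["bait"],
        replicate_sets=None,
        consensus=frozenset(consensus),
        support=support,
        mean_s=mean_s,
        category=meta["category"],
        k=k,
        fp_expected=float(meta["fp_expected"]),
    )


# -- Perturbation report persistence -----------------------------------------

def write_report(report, values_path: str | Path, verdicts_path: str | Path | None = None) -> None:
    """Write a perturbation report: per-replicate value table and verdicts.

    Values are numbers (SD-above-median score, 6 significant digits) or the
    codes ``P`` / ``ND``.
    """
    with open(values_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("bait\tmRNA\tcondition\treplicate\tvalue\n")
        for cell in report.cells:
            value = cell.value if isinstance(cell.value, str) else f"{cell.value:.6g}"
            fh.write(f"{cell.bait}\t{cell.mrna}\t{cell.condition}\t{cell.replicate}\t{value}\n")
    if verdicts_path is not None:
        with open(verdicts_path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("bait\tmRNA\tbaseline\ttreated\tverdict\n")
            for v in report.verdicts:
                fh.write(f"{v.bait}\t{v.mrna}\t{v.baseline}\t{v.treated}\t{v.verdict}\n")
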