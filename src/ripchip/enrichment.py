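"""Per-gene enrichment ratios and score transforms.

For each gene the enrichment ratio R is the median over its surviving probes
of log10(IP signal / total-RNA reference signal).  Two score scales are
derived from the per-experiment distribution of R over all genes:

* z = (R − mean) / SD   — the plotting/normalisation scale (mean 0, SD 1);
* s = (R − median) / SD — "SD above the median enrichment", the selection
  scale used for target calling.

The same sample SD (n−1 denominator, about the mean) backs both scores, so
s − z is a constant offset across genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .array_io import SpotRecord
from .errors import BackgroundTooSmallError, DegenerateProfileError

logger = logging.getLogger(__name__)

#: Minimum number of genes required to estimate the background distribution.
DEFAULT_MIN_BACKGROUND = 200


@dataclass
class GeneEnrichmentProfile:
    """Per-gene median log10(IP/reference) ratios for one experiment."""

    experiment_id: str
    ratios: dict[str, float]
    n_probes: dict[str, int]
    n_excluded_spots: int = 0  # spots dropped for non-positive signal

    @property
    def n_genes(self) -> int:
        return len(self.ratios)

    def genes(self) -> list[str]:
        return list(self.ratios)


@dataclass
class StandardizedProfile:
    """Standardised (z) and SD-above-median (s) scores for one experiment."""

    experiment_id: str
    z: dict[str, float]
    s: dict[str, float]
    mean_R: float
    median_R: float
    sd_R: float
    profile: GeneEnrichmentProfile | None = None

    @property
    def n_genes(self) -> int:
        return len(self.z)


@dataclass(frozen=True)
class BoxplotStats:
    """Box-plot summary: quartiles, 1.5×IQR whiskers, individual outliers."""

    median: float
    lower_quartile: float
    upper_quartile: float
    lower_whisker: float
    upper_whisker: float
    outliers: tuple[float, ...]


def gene_log_ratios(
    spots_by_gene: Mapping[str, Sequence[SpotRecord]],
    dye_swapped: bool = False,
    experiment_id: str = "",
) -> GeneEnrichmentProfile:
    """Median log10 ratio per gene over QC-surviving spots.

    Spots with a non-positive signal in either channel are excluded (counted,
    never clamped); genes whose spots are all excluded are dropped from the
    profile with a log message.  With ``dye_swapped`` true the per-spot ratio
    is inverted before the log (channel roles exchanged).
    """
    ratios: dict[str, float] = {}
    n_probes: dict[str, int] = {}
    n_excluded = 0
    for gene, spots in spots_by_gene.items():
        vals: list[float] = []
        for spot in spots:
            ip, ref = spot.ip_signal, spot.ref_signal
            if dye_swapped:
                ip, ref = ref, ip
            if ip <= 0 or ref <= 0:
                n_excluded += 1
                continue
            vals.append(math.log10(ip / ref))
        if vals:
            ratios[gene] = float(np.median(vals))
            n_probes[gene] = len(vals)
        else:
            logger.debug("gene %s dropped: all spots had non-positive signal", gene)
    return GeneEnrichmentProfile(
        experiment_id=experiment_id,
        ratios=ratios,
        n_probes=n_probes,
        n_excluded_spots=n_excluded,
    )


def standardize(
    profile: GeneEnrichmentProfile,
    min_background: int = DEFAULT_MIN_BACKGROUND,
) -> StandardizedProfile:
    """Standardise a profile to z (mean 0 / SD 1) and s (SD above median).

    Raises :class:`BackgroundTooSmallError` when fewer than ``min_background``
    genes are present and :class:`DegenerateProfileError` when the background
    has no spread.
    """
    n = profile.n_genes
    if n < min_background:
        raise BackgroundTooSmallError(n, min_background)
    genes = list(profile.ratios)
    values = np.asarray([profile.ratios[g] for g in genes], dtype=float)
    mean_R = float(np.mean(values))
    median_R = float(np.median(values))
    sd_R = float(np.std(values, ddof=1))
    if not np.isfinite(sd_R) or sd_R <= 0.0:
        raise DegenerateProfileError(
            f"profile {profile.experiment_id!r}: background SD is zero"
        )
    z = (values - mean_R) / sd_R
    s = (values - median_R) / sd_R
    return StandardizedProfile(
        experiment_id=profile.experiment_id,
        z={g: float(v) for g, v in zip(genes, z)},
        s={g: float(v) for g, v in zip(genes, s)},
        mean_R=mean_R,
        median_R=median_R,
        sd_R=sd_R,
        profile=profile,
    )


def boxplot_stats(values: Iterable[float]) -> BoxplotStats:
    """Box-plot statistics: type-7 quartiles, whiskers at the most extreme
    data values within 1.5×IQR of the quartiles, everything beyond reported
    individually as outliers."""
    v = np.asarray(sorted(values), dtype=float)
    if v.size < 2:
        raise ValueError("boxplot_stats requires at least 2 values")
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation (type 7)
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    within = v[(v >= lo_fence) & (v <= hi_fence)]
    lower_whisker = float(within.min())
    upper_whisker = float(within.max())
    outliers = tuple(float(x) for x in v[(v < lower_whisker) | (v > upper_whisker)])
    return BoxplotStats(
        median=float(med),
        lower_quartile=float(q1),
        upper_quartile=float(q3),
        lower_whisker=lower_whisker,
        upper_whisker=upper_whisker,
        outliers=outliers,
    )


def write_profile(std: StandardizedProfile, path) -> None:
    """Write a standardised profile TSV: gene_id, R, z, s, n_probes."""
    prof = std.profile
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\tR\tz\ts\tn_probes\n")
        for gene in std.z:
            r = prof.ratios[gene] if prof is not None else float("nan")
            n = prof.n_probes.get(gene, 0) if prof is not None else 0
            fh.write(f"{gene}\t{r:.6g}\t{std.z[gene]:.6g}\t{std.s[gene]:.6g}\t{n}\n")
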