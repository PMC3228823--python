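"""Platform-specific spot-quality filtering.

A spot is kept when both channels show a sufficient fraction of foreground
pixels above background (IP and total-RNA reference thresholds), or when the
IP channel alone clears the stricter stand-alone threshold.  Thresholds are
inclusive.  Scanner-flagged spots (flag < 0) are dropped before the pixel
rules apply.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .array_io import ArrayScan, PlatformSpec, SpotRecord, get_platform

REASON_FLAGGED = "flagged"
REASON_LOW_IP = "low_ip_frac"
REASON_LOW_REF = "low_ref_frac"


def spot_passes_qc(spot: SpotRecord, platform: PlatformSpec | str) -> bool:
    """Pixel-quality rule for a single spot (flag ignored here).

    pass ⇔ (ip_frac ≥ min_frac_ip AND ref_frac ≥ min_frac_ref)
           OR ip_frac ≥ min_frac_ip_alone
    """
    p = get_platform(platform)
    return (
        spot.ip_frac_above_bg >= p.min_frac_ip
        and spot.ref_frac_above_bg >= p.min_frac_ref
    ) or spot.ip_frac_above_bg >= p.min_frac_ip_alone


def is_ip_detectable(spot: SpotRecord, platform: PlatformSpec | str) -> bool:
    """An mRNA counts as detectable in the IP when the spot's IP-channel
    pixel fraction meets the stand-alone IP threshold."""
    return spot.ip_frac_above_bg >= get_platform(platform).min_frac_ip_alone


@dataclass(frozen=True)
class QCEntry:
    spot: SpotRecord
    kept: bool
    reason: str | None  # set only when not kept
    ip_detectable: bool


@dataclass
class QCResult:
    """Per-spot QC outcome; ``kept`` and ``removed`` partition the input."""

    entries: list[QCEntry]

    @property
    def kept(self) -> list[SpotRecord]:
        return [e.spot for e in self.entries if e.kept]

    @property
    def removed(self) -> list[tuple[SpotRecord, str]]:
        return [(e.spot, e.reason) for e in self.entries if not e.kept]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": [e.spot.probe_id for e in self.entries],
                "kept": [int(e.kept) for e in self.entries],
                "reason": [e.reason or "" for e in self.entries],
                "ip_detectable": [int(e.ip_detectable) for e in self.entries],
            }
        )


def filter_scan(scan: ArrayScan, platform: PlatformSpec | str | None = None) -> QCResult:
    """Apply the spot filters to a whole scan.

    Reason codes use fixed precedence: flagged > low_ip_frac > low_ref_frac.
    ``ip_detectable`` is recorded for every spot, pass or fail, because the
    perturbation layer needs it for ND coding.
    """
    if not scan.spots:
        raise ValueError(f"scan {scan.experiment_id!r} has no spots")
    p = get_platform(platform if platform is not None else scan.platform)
    entries: list[QCEntry] = []
    for spot in scan.spots:
        detectable = is_ip_detectable(spot, p)
        if spot.flag < 0:
            entries.append(QCEntry(spot, False, REASON_FLAGGED, detectable))
        elif spot_passes_qc(spot, p):
            entries.append(QCEntry(spot, True, None, detectable))
        elif spot.ip_frac_above_bg < p.min_frac_ip:
            entries.append(QCEntry(spot, False, REASON_LOW_IP, detectable))
        else:
            entries.append(QCEntry(spot, False, REASON_LOW_REF, detectable))
    return QCResult(entries)
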