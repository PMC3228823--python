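"""Replicate-consistent calling of bait-associated mRNAs.

A gene is called enriched in one experiment when its SD-above-median score s
is at least tau (default 2, inclusive).  Only genes that pass the threshold
in every independent biological replicate enter the consensus; common
contaminants are subtracted afterwards.  Under independence the expected
fraction of false positives in a k-replicate consensus is p^k, with p the
assumed single-replicate false-positive fraction (default 0.05; the
calibrated one-sided normal tail beyond tau SD is reported alongside, see
:func:`one_sided_normal_tail`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from scipy.stats import norm

from .array_io import Blacklist
from .enrichment import StandardizedProfile
from .errors import ConfigError

CATEGORY_EMPTY = "empty"
CATEGORY_BAIT_ONLY = "bait_only"
CATEGORY_TARGETS = "targets"


@dataclass(frozen=True)
class CallParameters:
    """tau: selection threshold in SD units; p: assumed per-replicate
    false-positive fraction; k: number of independent biological replicates."""

    tau: float = 2.0
    p: float = 0.05
    k: int = 1

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ConfigError(f"tau must be positive, got {self.tau}")
        if not 0.0 <= self.p <= 1.0:
            raise ConfigError(f"p must be in [0, 1], got {self.p}")
        if self.k < 1:
            raise ConfigError(f"k must be >= 1, got {self.k}")


@dataclass
class CallSet:
    """Consensus of per-replicate enriched sets for one bait."""

    bait_gene: str
    replicate_sets: list[frozenset[str]] | None
    consensus: frozenset[str]
    support: dict[str, tuple[int, int]]  # gene -> (replicates supporting, k)
    mean_s: dict[str, float]
    category: str
    k: int
    fp_expected: float


def call_enriched(profile: StandardizedProfile, params: CallParameters) -> set[str]:
    """Genes whose s score is at least tau (inclusive) in one experiment."""
    tau = params.tau
    return {g for g, s in profile.s.items() if s >= tau}


def intersect_replicates(
    call_sets: Sequence[set[str] | frozenset[str]],
    blacklist: Blacklist | None = None,
    bait_gene: str | None = None,
) -> frozenset[str]:
    """Intersection over replicates, then blacklist subtraction.

    Warns when a consensus containing non-bait genes rests on a single
    replicate: experiments detecting mRNAs beyond the bait's own are expected
    to be repeated at least twice.
    """
    if not call_sets:
        raise ValueError("at least one replicate call set is required")
    consensus: set[str] = set(call_sets[0])
    for cs in call_sets[1:]:
        consensus &= set(cs)
    if blacklist is not None:
        consensus -= set(blacklist.gene_ids)
    if len(call_sets) == 1 and any(g != bait_gene for g in consensus):
        warnings.warn(
            "non-bait consensus genes rest on a single replicate; "
            "replicate the experiment before trusting these calls",
            stacklevel=2,
        )
    return frozenset(consensus)


def replicate_support(
    call_sets: Sequence[set[str] | frozenset[str]],
) -> dict[str, tuple[int, int]]:
    """Per-gene replicate support over the union of all replicate sets."""
    k = len(call_sets)
    union: set[str] = set().union(*call_sets) if call_sets else set()
    return {g: (sum(g in cs for cs in call_sets), k) for g in union}


def classify_bait(consensus: Iterable[str], bait_gene: str) -> str:
    """empty (no enriched mRNA), bait_only (cognate mRNA only), or targets."""
    consensus = set(consensus)
    if not consensus:
        return CATEGORY_EMPTY
    if consensus == {bait_gene}:
        return CATEGORY_BAIT_ONLY
    return CATEGORY_TARGETS


def expected_false_positive_fraction(params: CallParameters) -> float:
    """Expected false-positive fraction of a k-replicate consensus: p**k."""
    return params.p ** params.k


def one_sided_normal_tail(tau: float = 2.0) -> float:
    """Calibrated single-replicate rate for a one-sided threshold at tau SD
    above the centre of a normal background (≈ 0.0228 at tau = 2)."""
    return float(norm.sf(tau))


def build_callset(
    profiles: Sequence[StandardizedProfile],
    bait_gene: str,
    params: CallParameters | None = None,
    blacklist: Blacklist | None = None,
) -> CallSet:
    """Run the full calling stage over replicate profiles for one bait."""
    if not profiles:
        raise ValueError("at least one replicate profile is required")
    params = replace(params or CallParameters(), k=len(profiles))
    sets = [frozenset(call_enriched(p, params)) for p in profiles]
    consensus = intersect_replicates(sets, blacklist, bait_gene=bait_gene)
    support = replicate_support(sets)
    mean_s = {
        g: sum(p.s[g] for p in profiles if g in p.s)
        / max(1, sum(g in p.s for p in profiles))
        for g in consensus
    }
    return CallSet(
        bait_gene=bait_gene,
        replicate_sets=sets,
        consensus=consensus,
        support={g: support.get(g, (params.k, params.k)) for g in consensus},
        mean_s=mean_s,
        category=classify_bait(consensus, bait_gene),
        k=params.k,
        fp_expected=expected_false_positive_fraction(params),
    )


def derive_contaminant_blacklist(
    consensus_by_bait: Mapping[str, Iterable[str]],
    min_baits: int = 4,
    min_fraction: float = 0.5,
) -> Blacklist:
    """Reconstruct a contaminant blacklist from call sets of unrelated baits.

    A gene is blacklisted when it was called enriched for at least
    ``min_fraction`` of the baits unrelated to it; each bait's cognate mRNA
    is exempt from counting in its own experiments.
    """
    baits = {b: set(genes) for b, genes in consensus_by_bait.items()}
    if len(baits) < min_baits:
        raise ValueError(
            f"need call sets from at least {min_baits} distinct baits, got {len(baits)}"
        )
    candidates: set[str] = set().union(*baits.values()) if baits else set()
    contaminants: set[str] = set()
    for gene in candidates:
        unrelated = [b for b in baits if b != gene]
        if not unrelated:
            continue
        n_called = sum(gene in baits[b] for b in unrelated)
        if n_called / len(unrelated) >= min_fraction:
            contaminants.add(gene)
    return Blacklist(frozenset(contaminants))


def summarize_fraction_with_targets(categories: Iterable[str]) -> float:
    """Percentage of baits whose consensus contains non-cognate mRNAs."""
    cats = list(categories)
    if not cats:
        raise ValueError("no bait categories given")
    return 100.0 * sum(c == CATEGORY_TARGETS for c in cats) / len(cats)
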