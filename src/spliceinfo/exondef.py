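"""Exon definition: gap surprisal, total exon information, isoform ranking,
and branch-point scanning.

The total information of a candidate exon is

    R_i,total = R_i,acceptor + R_i,donor - GS(length)
                [+ R_i,regulatory - GS_reg(distance)]

where the gap surprisal GS(L) = -log2 P(L) is the self-information of the
exon length under an empirical length distribution: exons of uncommon
length are penalized, so exons are computationally defined by donor and
acceptor sites in close proximity.  An optional regulatory-element term
adds the strongest binding site of a single splicing factor, discounted by
a second surprisal over its distance to the nearest natural splice site.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .infomodel import InfoModel
from .scoring import ScoredSite, scan, score_site, site_span
from .variants import VariantRecord, apply_variant

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Gap surprisal
# ---------------------------------------------------------------------------


@dataclass
class GapSurprisalModel:
    """Binned length (or distance) distribution for self-information lookups.

    ``edges`` are increasing upper bin edges in nt; bin i covers
    (edges[i-1], edges[i]] with an implicit lower edge of 0.  Lengths beyond
    the last edge are handled by ``tail_policy``: 'floor' charges the floor
    probability, 'last_bin' reuses the final bin.
    """

    kind: str  # 'exon_length' or 'regulatory_distance'
    edges: np.ndarray
    probabilities: np.ndarray
    tail_policy: str = "floor"
    floor_probability: float = 2.0**-20

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.kind not in ("exon_length", "regulatory_distance"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if len(self.edges) != len(self.probabilities):
            raise ValueError("edges and probabilities must have equal length")
        if (np.diff(self.edges) <= 0).any():
            raise ValueError("bin edges must be strictly increasing")
        if (self.probabilities < 0).any():
            raise ValueError("bin probabilities must be non-negative")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"bin probabilities sum to {self.probabilities.sum():.12f}, not 1"
            )
        if self.tail_policy not in ("floor", "last_bin"):
            raise ValueError(f"unknown tail policy {self.tail_policy!r}")

    def probability(self, length: int) -> float:
        if length < 1:
            raise ValueError("lengths are >= 1 nt")
        if length > self.edges[-1]:
            if self.tail_policy == "last_bin":
                p = self.probabilities[-1]
            else:
                p = self.floor_probability
        else:
            i = int(np.searchsorted(self.edges, length, side="left"))
            p = self.probabilities[i]
        return float(max(p, self.floor_probability))

    def surprisal(self, length: int) -> float:
        return -math.log2(self.probability(length))

    @classmethod
    def from_lengths(cls, lengths, *, kind: str = "exon_length", edges=None,
                     **kwargs) -> "GapSurprisalModel":
        """Empirical model from observed lengths, default log-spaced bins."""
        edges = np.asarray(edges if edges is not None else default_edges(), dtype=int)
        lengths = np.asarray(lengths, dtype=int)
        if len(lengths) == 0:
            raise ValueError("no lengths supplied")
        idx = np.searchsorted(edges, np.clip(lengths, 1, edges[-1]), side="left")
        counts = np.bincount(idx, minlength=len(edges)).astype(float)
        return cls(kind=kind, edges=edges, probabilities=counts / counts.sum(), **kwargs)

    @classmethod
    def from_table(cls, table: pd.DataFrame, *, kind: str = "exon_length",
                   **kwargs) -> "GapSurprisalModel":
        """Two-column table: upper bin edge (nt), probability."""
        edges = table.iloc[:, 0].to_numpy(dtype=int)
        probs = table.iloc[:, 1].to_numpy(dtype=float)
        return cls(kind=kind, edges=edges, probabilities=probs, **kwargs)

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame({"upper_edge": self.edges, "probability": self.probabilities})


def default_edges(n_bins: int = 16, max_nt: int = 10_000) -> np.ndarray:
    """Log-spaced upper bin edges over [1, max_nt]."""
    edges = np.unique(np.round(np.logspace(0, math.log10(max_nt), n_bins)).astype(int))
    return edges


def default_exon_length_model() -> GapSurprisalModel:
    """Synthetic stand-in for the genome-wide constitutive exon length
    distribution: log-normal with median 120 nt (sigma 0.6 in log units),
    integrated over the default bins.  Substitute a real table for
    production use.
    """
    edges = default_edges()
    dist = _stats.lognorm(s=0.6, scale=120.0)
    upper = edges.astype(float)
    lower = np.concatenate([[0.0], upper[:-1]])
    probs = dist.cdf(upper) - dist.cdf(lower)
    probs = probs / probs.sum()
    return GapSurprisalModel(kind="exon_length", edges=edges, probabilities=probs)


def default_regulatory_distance_model() -> GapSurprisalModel:
    """Distance-from-nearest-natural-site distribution for regulatory
    elements, concentrated within ~10 nt with a monotone-increasing penalty
    (exponential with 10-nt scale, integrated over short bins).
    """
    edges = np.array([5, 10, 20, 50, 100, 200, 400])
    dist = _stats.expon(scale=10.0)
    upper = edges.astype(float)
    lower = np.concatenate([[0.0], upper[:-1]])
    probs = dist.cdf(upper) - dist.cdf(lower)
    probs = probs / probs.sum()
    return GapSurprisalModel(kind="regulatory_distance", edges=edges, probabilities=probs)


def gap_surprisal(model: GapSurprisalModel, length: int) -> float:
    """-log2 of the probability of the bin containing ``length`` (bits)."""
    return model.surprisal(length)


# ---------------------------------------------------------------------------
# Exon candidates
# ---------------------------------------------------------------------------


@dataclass
class RegulatoryTerm:
    factor: str
    r_i: float
    distance_nt: int
    surprisal: float


@dataclass
class ExonCandidate:
    acceptor: ScoredSite
    donor: ScoredSite
    length: int
    gap_surprisal: float
    regulatory: RegulatoryTerm | None
    r_i_total: float
    is_wild_type: bool = False


def exon_length(acceptor_zero: int, donor_zero: int) -> int:
    """Exonic bases between the two zero points.

    The acceptor zero point is the last intronic base and the donor zero
    point the first intronic base, so the exon spans
    [acceptor_zero + 1, donor_zero - 1] inclusive.
    """
    return donor_zero - acceptor_zero - 1


def exon_total(
    acceptor: ScoredSite,
    donor: ScoredSite,
    gs_model: GapSurprisalModel,
    regulatory=None,
    *,
    is_wild_type: bool = False,
) -> ExonCandidate:
    """Total exon information for an acceptor/donor pair.

    ``regulatory``, if given, is a tuple ``(factor_name, sites,
    distance_model)`` where ``sites`` is a list of ScoredSite for one factor
    (e.g. the same element scored before and after a variant); the strongest
    is chosen and discounted by the distance surprisal to the nearest of the
    two splice sites.
    """
    if donor.zero_coord <= acceptor.zero_coord:
        raise ValueError(
            f"donor (at {donor.zero_coord}) must lie downstream of acceptor "
            f"(at {acceptor.zero_coord})"
        )
    length = exon_length(acceptor.zero_coord, donor.zero_coord)
    if length < 1:
        raise ValueError("exon length must be >= 1 nt")
    gs = gs_model.surprisal(length)
    total = acceptor.r_i + donor.r_i - gs
    reg_term = None
    if regulatory is not None:
        factor, sites, dist_model = regulatory
        if not sites:
            raise ValueError("regulatory term requested but no sites supplied")
        best = max(sites, key=lambda s: s.r_i)
        distance = min(abs(best.zero_coord - acceptor.zero_coord),
                       abs(best.zero_coord - donor.zero_coord))
        reg_gs = dist_model.surprisal(max(distance, 1))
        reg_term = RegulatoryTerm(factor=factor, r_i=best.r_i,
                                  distance_nt=distance, surprisal=reg_gs)
        total += best.r_i - reg_gs
    return ExonCandidate(
        acceptor=acceptor,
        donor=donor,
        length=length,
        gap_surprisal=gs,
        regulatory=reg_term,
        r_i_total=total,
        is_wild_type=is_wild_type,
    )


# ---------------------------------------------------------------------------
# Isoform ranking
# ---------------------------------------------------------------------------


@dataclass
class Isoform:
    isoform_type: str  # 'exon' or 'skipping'
    candidate: ExonCandidate | None
    rank: int
    phase: str  # 'pre' or 'post'

    def to_dict(self) -> dict:
        d: dict = {"isoform_type": self.isoform_type, "rank": self.rank, "phase": self.phase}
        if self.candidate is not None:
            c = self.candidate
            d.update(
                {
                    "acceptor_coordinate": c.acceptor.zero_coord + 1,
                    "donor_coordinate": c.donor.zero_coord + 1,
                    "length": c.length,
                    "acceptor_ri": c.acceptor.r_i,
                    "donor_ri": c.donor.r_i,
                    "gap_surprisal": c.gap_surprisal,
                    "r_i_total": c.r_i_total,
                    "wild_type": c.is_wild_type,
                }
            )
        return d


def _rank_candidates(cands: list[ExonCandidate], phase: str) -> list[Isoform]:
    cands = sorted(
        cands,
        key=lambda c: (-c.r_i_total, c.length, c.acceptor.zero_coord),
    )
    return [Isoform("exon", c, rank=i + 1, phase=phase) for i, c in enumerate(cands)]


def rank_isoforms(
    reference: str,
    v: VariantRecord,
    *,
    acceptor_model: InfoModel,
    donor_model: InfoModel,
    natural_acceptor: int,
    natural_donor: int,
    gs_model: GapSurprisalModel,
    r_i_min: float = 1.6,
    skip_threshold_bits: float = 7.0,
    search_nt: int = 100,
    min_exon_nt: int = 10,
) -> dict[str, list[Isoform]]:
    """Rank candidate exon isoforms before and after a variant.

    Candidate exons are formed from every acceptor/donor pair with
    R_i >= ``r_i_min`` found within ``search_nt`` of the annotated natural
    exon, plus the natural pair itself; they are ordered by descending
    R_i,total (ties: shorter exon, then lower coordinate).  When the variant
    weakens a natural site by at least ``skip_threshold_bits`` (>= 128-fold
    at the 7-bit default) the exon-skipping isoform is inserted at the top
    of the post-variant ranking.
    """
    if natural_donor <= natural_acceptor:
        raise ValueError("natural donor must lie downstream of the natural acceptor")

    applied = apply_variant(reference, v)

    def candidates(seq: str, acc_zero: int, don_zero: int) -> list[ExonCandidate]:
        lo = max(0, acc_zero - search_nt)
        hi = don_zero + search_nt
        accs = {s.zero_coord: s for s in scan(acceptor_model, seq, r_i_min, (lo, hi + 1))}
        dons = {s.zero_coord: s for s in scan(donor_model, seq, r_i_min, (lo, hi + 1))}
        for zero, model, pool in ((acc_zero, acceptor_model, accs),
                                  (don_zero, donor_model, dons)):
            if zero not in pool:
                try:
                    pool[zero] = score_site(model, seq, zero)
                except ValueError:
                    pass
        out = []
        for a in accs.values():
            for d in dons.values():
                if d.zero_coord - a.zero_coord - 1 < min_exon_nt:
                    continue
                wild = a.zero_coord == acc_zero and d.zero_coord == don_zero
                out.append(exon_total(a, d, gs_model, is_wild_type=wild))
        return out

    pre_list = _rank_candidates(candidates(reference, natural_acceptor, natural_donor), "pre")

    acc_post = applied.map_coord0(natural_acceptor)
    don_post = applied.map_coord0(natural_donor)
    # re-anchor a deleted zero point to the nearest surviving base
    if acc_post < 0:
        acc_post = next((applied.map_coord0(p) for p in range(natural_acceptor, len(reference))
                         if applied.map_coord0(p) >= 0), -1)
    if don_post < 0:
        don_post = next((applied.map_coord0(p) for p in range(natural_donor, -1, -1)
                         if applied.map_coord0(p) >= 0), -1)

    post_cands = candidates(applied.sequence, acc_post, don_post) if acc_post >= 0 and don_post > acc_post else []
    post_list = _rank_candidates(post_cands, "post")

    # natural-site drop decides whether skipping is displayed first
    drop = 0.0
    for model, zero, new_zero in ((acceptor_model, natural_acceptor, acc_post),
                                  (donor_model, natural_donor, don_post)):
        try:
            pre_ri = score_site(model, reference, zero).r_i
            post_ri = score_site(model, applied.sequence, new_zero).r_i if new_zero >= 0 else -math.inf
        except ValueError:
            continue
        drop = max(drop, pre_ri - post_ri)
    if drop >= skip_threshold_bits or not post_list:
        skip = Isoform("skipping", None, rank=1, phase="post")
        for iso in post_list:
            iso.rank += 1
        post_list = [skip] + post_list
    return {"pre": pre_list, "post": post_list}


# ---------------------------------------------------------------------------
# Branch points
# ---------------------------------------------------------------------------


@dataclass
class BranchPointHit:
    site: ScoredSite
    distance_to_acceptor: int
    context_ok: bool


def find_branchpoints(
    bps_model: InfoModel,
    sequence: str,
    acceptor_zero: int,
    *,
    search_nt: int = 100,
    hard_max_nt: int = 400,
    donor_windows=(),
    min_ri: float = 0.0,
) -> list[BranchPointHit]:
    """Scan for branch-point sites upstream of an annotated acceptor.

    The branch point is typically within 40 nt of the acceptor but can lie
    up to ~400 nt away; hits beyond ``hard_max_nt`` are never returned.
    Hits whose window overlaps an annotated donor window are flagged
    ``context_ok=False`` — splice-site-like sequence inside a donor is a
    known source of spurious branch-point calls.  Sorted by descending R_i,
    ties broken by proximity to the acceptor.
    """
    reach = min(search_nt, hard_max_nt)
    lo = max(0, acceptor_zero - reach)
    hits = scan(bps_model, sequence, min_ri, (lo, acceptor_zero + 1))
    out = []
    for h in hits:
        distance = acceptor_zero - h.zero_coord
        if distance < 0 or distance > reach:
            continue
        span = site_span(bps_model, h.zero_coord, h.strand)
        ok = True
        for dstart, dend in donor_windows:
            if span[0] < dend and dstart < span[1]:
                ok = False
                break
        out.append(BranchPointHit(site=h, distance_to_acceptor=distance, context_ok=ok))
    out.sort(key=lambda b: (-b.site.r_i, b.distance_to_acceptor))
    return out
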