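"""Scoring candidate binding sites and scanning sequences.

R_i of a placement is the dot product of the model weights with the one-hot
encoding of the sequence window; per-position contributions (the "sequence
walker" decomposition) are retained so that the bases arguing for and
against binding can be reported individually.

Coordinates are 0-based internally; file readers/writers convert to 1-based
inclusive.  A site is addressed by the coordinate of its model zero point
(the intron-side base at the splice junction); on the minus strand the
window extends in the opposite direction and is read as the reverse
complement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .infomodel import BASE_INDEX, BASES, InfoModel

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ScoredSite:
    """One scored placement of a model on a sequence."""

    model_name: str
    site_kind: str
    zero_coord: int  # 0-based position of the model zero point on the scanned sequence
    strand: str
    r_i: float
    contributions: np.ndarray
    window_seq: str
    has_ambiguous: bool = False

    def __post_init__(self) -> None:
        self.contributions = np.asarray(self.contributions, dtype=float)


def _window_span(model: InfoModel, zero_coord: int, strand: str) -> tuple[int, int]:
    """Half-open span of sequence positions covered by the window."""
    if strand == "+":
        return zero_coord + model.offset_start, zero_coord + model.offset_end + 1
    if strand == "-":
        return zero_coord - model.offset_end, zero_coord - model.offset_start + 1
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def site_span(model: InfoModel, zero_coord: int, strand: str = "+") -> tuple[int, int]:
    """Public helper: half-open [start, end) covered by a placement."""
    return _window_span(model, zero_coord, strand)


def score_site(model: InfoModel, sequence: str, zero_coord: int, strand: str = "+") -> ScoredSite:
    """Score one placement of ``model`` with its zero point at ``zero_coord``.

    Ambiguous bases (N) contribute 0 bits at their position and set the
    ``has_ambiguous`` flag, keeping R_i conservative.
    """
    start, end = _window_span(model, zero_coord, strand)
    if start < 0 or end > len(sequence):
        pad_left = max(0, -start)
        pad_right = max(0, end - len(sequence))
        raise ValueError(
            f"window [{start}, {end}) out of bounds for sequence of length "
            f"{len(sequence)}; requires {pad_left} nt padding upstream and "
            f"{pad_right} nt downstream"
        )
    window = sequence[start:end].upper().replace("U", "T")
    if strand == "-":
        window = reverse_complement(window)

    contributions = np.zeros(model.length)
    ambiguous = False
    for i, base in enumerate(window):
        j = BASE_INDEX.get(base)
        if j is None:
            ambiguous = True
            continue
        contributions[i] = model.weights[i, j]
    return ScoredSite(
        model_name=model.name,
        site_kind=model.site_kind,
        zero_coord=zero_coord,
        strand=strand,
        r_i=float(contributions.sum()),
        contributions=contributions,
        window_seq=window,
        has_ambiguous=ambiguous,
    )


def _encode(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.upper().replace("U", "T").encode(), dtype=np.uint8)
    idx = np.full(arr.shape, 4, dtype=np.int64)
    for base, j in BASE_INDEX.items():
        idx[arr == ord(base)] = j
    return idx


def _plus_strand_scores(model: InfoModel, idx: np.ndarray) -> np.ndarray:
    """Score every window start 0..n-L; N columns contribute 0 bits."""
    L = model.length
    m = len(idx) - L + 1
    if m <= 0:
        return np.empty(0)
    w_ext = np.hstack([model.weights, np.zeros((L, 1))])
    scores = np.zeros(m)
    for l in range(L):
        scores += w_ext[l, idx[l : l + m]]
    return scores


def scan(
    model: InfoModel,
    sequence: str,
    min_ri: float = -math.inf,
    region: tuple[int, int] | None = None,
    strand: str = "+",
) -> list[ScoredSite]:
    """All placements with R_i >= ``min_ri``, sorted by zero coordinate.

    ``region`` is a half-open interval restricting the *zero coordinates*
    considered; the window itself must still fit inside the sequence.
    Equivalent to brute-force ``score_site`` at every valid offset.
    """
    n = len(sequence)
    if strand == "-":
        mirrored = None if region is None else (n - region[1], n - region[0])
        hits_rc = scan(model, reverse_complement(sequence), min_ri, mirrored, "+")
        out = []
        for h in hits_rc:
            out.append(
                ScoredSite(
                    model_name=h.model_name,
                    site_kind=h.site_kind,
                    zero_coord=n - 1 - h.zero_coord,
                    strand="-",
                    r_i=h.r_i,
                    contributions=h.contributions,
                    window_seq=h.window_seq,
                    has_ambiguous=h.has_ambiguous,
                )
            )
        out.sort(key=lambda s: s.zero_coord)
        return out

    idx = _encode(sequence)
    scores = _plus_strand_scores(model, idx)
    # window start s corresponds to zero coordinate z = s - offset_start
    z_lo = -model.offset_start
    z_hi = z_lo + len(scores)  # exclusive
    if region is not None:
        z_lo2, z_hi2 = max(z_lo, region[0]), min(z_hi, region[1])
    else:
        z_lo2, z_hi2 = z_lo, z_hi
    sites: list[ScoredSite] = []
    for z in range(z_lo2, max(z_lo2, z_hi2)):
        r = scores[z - z_lo]
        if r >= min_ri:
            sites.append(score_site(model, sequence, z, "+"))
    return sites


@dataclass
class WalkerEntry:
    offset: int
    base: str
    contribution: float
    sign: str  # '+', '-', or '0'


def walker(site: ScoredSite, model: InfoModel | None = None) -> list[WalkerEntry]:
    """Per-position walker report for a scored site.

    Negative contributions flag bases arguing against binding.  Offsets are
    taken from ``model`` when given, otherwise inferred cannot be; the
    entries are then numbered from 0.
    """
    if model is not None:
        offsets = list(model.offsets)
    else:
        offsets = list(range(len(site.contributions)))
    entries = []
    for off, base, c in zip(offsets, site.window_seq, site.contributions):
        sign = "0" if c == 0 else ("+" if c > 0 else "-")
        entries.append(WalkerEntry(offset=off, base=base, contribution=float(c), sign=sign))
    return entries


def sites_to_dataframe(sites: list[ScoredSite], seq_id: str = "") -> pd.DataFrame:
    """Tabular export with 1-based zero coordinates."""
    rows = [
        {
            "seq_id": seq_id,
            "coordinate": s.zero_coord + 1,
            "strand": s.strand,
            "site_kind": s.site_kind,
            "model": s.model_name,
            "r_i": s.r_i,
            "window": s.window_seq,
        }
        for s in sites
    ]
    return pd.DataFrame(
        rows, columns=["seq_id", "coordinate", "strand", "site_kind", "model", "r_i", "window"]
    )


def sites_to_json(sites: list[ScoredSite], seq_id: str = "") -> list[dict]:
    return [
        {
            "seq_id": seq_id,
            "coordinate": s.zero_coord + 1,
            "strand": s.strand,
            "site_kind": s.site_kind,
            "model": s.model_name,
            "r_i": s.r_i,
            "window": s.window_seq,
            "contributions": [float(c) for c in s.contributions],
        }
        for s in sites
    ]
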