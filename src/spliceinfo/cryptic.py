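"""Cryptic splice-site activation typing and genome-pipeline flagging.

Cryptic (decoy) splice sites are splice-site-like sequences not used in
constitutive splicing.  Variant-driven activation falls into three types:

* Type 1 — the cryptic site is strengthened or created while the natural
  site of the same polarity is unchanged;
* Type 2 — a single variant simultaneously weakens the natural site and
  strengthens/creates an overlapping cryptic site;
* Type 3 — the natural site is weakened and a pre-existing cryptic site
  (already above the functional minimum) takes over, itself untouched.

The genome-pipeline filter retains variants where the site has
R_i,initial or R_i,final >= 0 bits and |delta_ri| >= 1.0 bits, then
prioritizes weakened natural sites and cryptic sites whose strength is
comparable to or exceeding the nearest natural site of the same polarity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import (
    NaturalSite,
    SiteDelta,
    VariantRecord,
    analyze_variant,
)

logger = logging.getLogger(__name__)

EVENT_TYPES = ("type1", "type2", "type3", "none")


@dataclass
class CrypticEvent:
    event_type: str
    natural: SiteDelta
    cryptic: SiteDelta
    distance_nt: int
    same_polarity: bool
    competition_margin: float  # cryptic r_i_final - natural r_i_final


def classify_event(
    natural: SiteDelta,
    cryptic: SiteDelta,
    significance_bits: float = 1.0,
    r_i_min: float = 1.6,
) -> CrypticEvent:
    """Type a (natural, cryptic) delta pair; the rules partition all pairs.

    ``significance_bits`` is the experimental-detectability threshold below
    which a change counts as "unchanged" (this also resolves whether Type 1
    tolerates sub-significance drift of the natural site: it does).
    """
    if natural.site_kind != cryptic.site_kind:
        raise ValueError(
            f"polarity mismatch: natural is {natural.site_kind}, cryptic is "
            f"{cryptic.site_kind}"
        )
    cryptic_up = cryptic.delta_ri >= significance_bits
    natural_down = natural.delta_ri <= -significance_bits
    natural_unchanged = abs(natural.delta_ri) < significance_bits
    cryptic_unchanged = abs(cryptic.delta_ri) < significance_bits
    preexisting = cryptic.r_i_initial >= r_i_min

    if natural_down and cryptic_up:
        event_type = "type2"
    elif cryptic_up and natural_unchanged:
        event_type = "type1"
    elif natural_down and cryptic_unchanged and preexisting:
        event_type = "type3"
    else:
        event_type = "none"
    return CrypticEvent(
        event_type=event_type,
        natural=natural,
        cryptic=cryptic,
        distance_nt=cryptic.zero_coord - natural.zero_coord,
        same_polarity=True,
        competition_margin=cryptic.r_i_final - natural.r_i_final,
    )


@dataclass
class ActivationCall:
    call: str  # 'likely' or 'unlikely'
    rationale: str


def predict_activation(
    event: CrypticEvent,
    slack_bits: float = 1.0,
    *,
    r_i_min: float = 1.6,
    distance_cutoff: int = 400,
) -> ActivationCall:
    """Will the typed cryptic site be used?

    Likely when the cryptic site is functional (>= r_i_min) and comparable
    to or exceeding the post-variant natural site ("comparable" = within
    ``slack_bits``); a cryptic site farther than ``distance_cutoff`` nt from
    the natural site is downgraded — distant sites are less likely to be
    recognized even when strong.
    """
    if event.event_type == "none":
        raise ValueError("activation is only assessed for typed events")
    cr = event.cryptic.r_i_final
    nat = event.natural.r_i_final
    if cr < r_i_min:
        return ActivationCall("unlikely", f"cryptic R_i,final {cr:.2f} bits < R_i,min {r_i_min}")
    if cr < nat - slack_bits:
        return ActivationCall(
            "unlikely",
            f"cryptic site {nat - cr:.2f} bits (>= {2 ** (nat - cr):.0f}-fold) weaker "
            f"than the natural site",
        )
    if abs(event.distance_nt) > distance_cutoff:
        return ActivationCall(
            "unlikely",
            f"cryptic site {abs(event.distance_nt)} nt from the natural site "
            f"(> {distance_cutoff} nt cutoff)",
        )
    return ActivationCall(
        "likely",
        f"cryptic R_i,final {cr:.2f} bits within {slack_bits} bits of (or exceeding) "
        f"the natural site at {abs(event.distance_nt)} nt",
    )


@dataclass
class FlagRecord:
    delta: SiteDelta
    retained: bool
    priority: int | None  # 1 = weakened natural, 2 = activatable cryptic, 3 = strengthened natural
    reason: str


def pipeline_flag(
    deltas,
    *,
    r_i_min: float = 1.6,
    significance_bits: float = 1.0,
    slack_bits: float = 1.0,
    distance_cutoff: int = 400,
) -> list[FlagRecord]:
    """Apply the genome-pipeline retention and prioritization rules.

    A delta is retained when (R_i,initial >= 0 or R_i,final >= 0) and
    |delta_ri| >= ``significance_bits``; retained deltas are then
    prioritized: weakened natural sites first, cryptic sites passing the
    activation test against the nearest natural site of the same polarity
    second, strengthened natural sites last (retained but unlikely to be
    deleterious).  Everything else is dropped with a reason code.  The
    operation is pure and order-independent.
    """
    deltas = list(deltas)
    naturals = [d for d in deltas if d.is_natural]
    records: list[FlagRecord] = []
    for d in deltas:
        if d.r_i_initial < 0 and d.r_i_final < 0:
            records.append(FlagRecord(d, False, None, "below_zero_bits"))
            continue
        if abs(d.delta_ri) < significance_bits:
            records.append(FlagRecord(d, False, None, "delta_below_1_bit"))
            continue
        if d.is_natural:
            if d.delta_ri < 0:
                records.append(FlagRecord(d, True, 1, "natural_site_weakened"))
            else:
                records.append(
                    FlagRecord(d, True, 3, "natural_site_strengthened_low_priority")
                )
            continue
        same_kind = [n for n in naturals if n.site_kind == d.site_kind and n.strand == d.strand]
        if not same_kind:
            if d.r_i_final >= r_i_min and d.delta_ri > 0:
                records.append(FlagRecord(d, True, 2, "cryptic_no_natural_reference"))
            else:
                records.append(FlagRecord(d, False, None, "cryptic_not_activatable"))
            continue
        nearest = min(same_kind, key=lambda n: abs(n.zero_coord - d.zero_coord))
        event = classify_event(nearest, d, significance_bits, r_i_min)
        if event.event_type == "none":
            records.append(FlagRecord(d, False, None, "no_cryptic_event"))
            continue
        call = predict_activation(event, slack_bits, r_i_min=r_i_min,
                                  distance_cutoff=distance_cutoff)
        if call.call == "likely":
            records.append(FlagRecord(d, True, 2, f"cryptic_activatable: {call.rationale}"))
        else:
            records.append(FlagRecord(d, False, None, f"cryptic_unlikely: {call.rationale}"))
    return records


def flagged(records: list[FlagRecord]) -> list[SiteDelta]:
    return [r.delta for r in sorted(
        (r for r in records if r.retained),
        key=lambda r: (r.priority, r.delta.zero_coord),
    )]


def strength_differential_stats(events_with_location) -> pd.DataFrame:
    """Mean +/- sample SD of the competition margin per (type, location).

    Input: iterable of ``(CrypticEvent, location)`` with location in
    {'intronic', 'exonic'}.  The margin is cryptic R_i - natural R_i,final.
    Strata with fewer than 2 events get no SD; empty strata are omitted
    (with a logged notice when the input itself is empty).
    """
    rows = []
    for event, location in events_with_location:
        if location not in ("intronic", "exonic"):
            raise ValueError(f"unknown location label {location!r}")
        rows.append(
            {
                "event_type": event.event_type,
                "location": location,
                "margin": event.competition_margin,
            }
        )
    if not rows:
        logger.info("no events supplied; empty statistics")
        return pd.DataFrame(columns=["event_type", "location", "mean", "sd", "n"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["event_type", "location"])["margin"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else float("nan"), n="size")
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# End-to-end interpretation
# ---------------------------------------------------------------------------


@dataclass
class VariantInterpretation:
    label: str  # abolished / leaky / neutral / type1 / type2 / type3
    deltas: list[SiteDelta]
    events: list[CrypticEvent]


def interpret_variant(
    reference: str,
    v: VariantRecord,
    models,
    natural_sites,
    *,
    window_nt: int = 54,
    r_i_min: float = 1.6,
    significance_bits: float = 1.0,
    competition_slack_bits: float = 1.0,
    strand: str = "+",
) -> VariantInterpretation:
    """Analyze a variant and reduce the per-site deltas to a single call.

    Typed cryptic events dominate; otherwise the strongest natural-site
    category (abolished > leaky) is reported, else neutral.  A Type 2 call
    additionally requires the variant footprint to intersect both site
    windows ("simultaneous" change); a distant, independently changing site
    falls back to the natural-site rule.

    An event is only reported as the call when its cryptic site is
    functional (>= ``r_i_min``) and competitive with the natural site's
    full (pre-variant) strength to within ``competition_slack_bits`` —
    activated cryptic sites are generally comparable to or stronger than
    their cognate natural sites, and the genome's ubiquitous weak decoys
    should not override an abolished/leaky call merely because they
    survive the variant.
    """
    deltas = analyze_variant(
        reference, v, models, natural_sites,
        window_nt=window_nt, r_i_min=r_i_min,
        significance_bits=significance_bits, strand=strand,
    )
    fstart, fend = v.span()
    foot = (fstart - 1, fend)  # half-open, 0-based

    events: list[CrypticEvent] = []
    naturals = [d for d in deltas if d.is_natural]
    for d in deltas:
        if d.is_natural:
            continue
        relevant = (
            d.category in ("cryptic_created", "cryptic_strengthened")
            or (d.r_i_initial >= r_i_min and abs(d.delta_ri) < significance_bits)
        )
        if not relevant:
            continue
        same_kind = [n for n in naturals if n.site_kind == d.site_kind and n.strand == d.strand]
        if not same_kind:
            continue
        nearest = min(same_kind, key=lambda n: abs(n.zero_coord - d.zero_coord))
        event = classify_event(nearest, d, significance_bits, r_i_min)
        if event.event_type == "type2":
            spans = [nearest.window_span, d.window_span]
            if not all(s is not None and s[0] < foot[1] and foot[0] < s[1] for s in spans):
                # not a shared-footprint change: re-type by the natural-site rule
                event.event_type = (
                    "type3" if d.r_i_initial >= r_i_min and abs(d.delta_ri) < significance_bits
                    else "none"
                )
        competitive = event.cryptic.r_i_final >= (
            max(nearest.r_i_initial, nearest.r_i_final) - competition_slack_bits
        )
        if event.event_type != "none" and event.cryptic.r_i_final >= r_i_min and competitive:
            events.append(event)

    if events:
        # a single variant rarely produces several typed events; report the
        # one with the strongest activated cryptic site
        best = max(events, key=lambda e: e.cryptic.r_i_final)
        label = best.event_type
    elif any(d.category == "abolished" for d in naturals):
        label = "abolished"
    elif any(d.category == "leaky" for d in naturals):
        label = "leaky"
    else:
        label = "neutral"
    return VariantInterpretation(label=label, deltas=deltas, events=events)
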