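"""Intron gain and loss in duplicated yeast genes after whole-genome duplication.

The budding-yeast whole-genome duplication (WGD, ~100 Mya) left S. cerevisiae
with hundreds of syntenic gene pairs (ohnologs).  For each pair, intron
presence/absence across six pre-WGD outgroup species (C. albicans,
L. waltii, L. thermotolerans, L. kluyveri, E. gossypii, K. lactis), the
protoploid Z. rouxii, and the post-WGD species (V. polyspora, N. castellii,
C. glabrata, S. bayanus, S. cerevisiae) lets one infer whether the pre-WGD
ancestral gene carried an intron, and hence whether the S. cerevisiae copies
have lost (0, 1 or 2 losses per pair) or gained introns since the
duplication.  A lower-tail exact binomial test then asks whether ribosomal
protein gene (RPG) pairs are depleted for losses relative to their share of
the at-risk pairs.

Ancestral inference is a majority rule:

    PRESENT  iff  a strict majority of non-missing outgroups have an intron
             AND (Z. rouxii has an intron OR a strict majority of
                  non-missing post-WGD species have >=1 intron in either copy)

Exact ties leave the call AMBIGUOUS; ambiguous pairs are excluded from
loss/gain counting.  Missing species never enter any denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

PRE_WGD_SPECIES = ("Ca", "Lw", "Lt", "Lk", "Eg", "Kl")
POST_WGD_SPECIES = ("Vp", "Nc", "Cg", "Sb", "Sc")

PRESENT = "PRESENT"
ABSENT = "ABSENT"
AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class OrthologRecord:
    """Intron counts for one WGD-derived gene pair across species.

    ``pre_wgd_counts`` maps outgroup species to an intron count or None
    (missing ortholog); ``post_wgd_counts`` maps post-WGD species to a pair
    of per-copy counts (a singleton gene may be encoded as (n, None)) or
    None.  The S. cerevisiae pair itself lives under key "Sc".
    """

    pair_id: str
    gene_a: str
    gene_b: str
    gene_class: str
    pre_wgd_counts: Mapping[str, int | None]
    zr_count: int | None
    post_wgd_counts: Mapping[str, tuple[int | None, int | None] | None]

    def __post_init__(self) -> None:
        if self.gene_class not in ("RPG", "non-RPG"):
            raise ValueError(f"unknown gene class {self.gene_class!r}")
        for v in self.pre_wgd_counts.values():
            if v is not None and v < 0:
                raise ValueError("negative intron count")
        for pair in self.post_wgd_counts.values():
            if pair is not None:
                for v in pair:
                    if v is not None and v < 0:
                        raise ValueError("negative intron count")
        if self._all_missing():
            raise ValueError(f"{self.pair_id}: all species missing")

    def _all_missing(self) -> bool:
        if any(v is not None for v in self.pre_wgd_counts.values()):
            return False
        if self.zr_count is not None:
            return False
        return all(v is None for v in self.post_wgd_counts.values())

    @property
    def sc_counts(self) -> tuple[int | None, int | None] | None:
        return self.post_wgd_counts.get("Sc")

    def swapped(self) -> "OrthologRecord":
        """Same record with the two S. cerevisiae copy labels exchanged."""
        post = dict(self.post_wgd_counts)
        sc = post.get("Sc")
        if sc is not None:
            post["Sc"] = (sc[1], sc[0])
        return OrthologRecord(self.pair_id, self.gene_b, self.gene_a,
                              self.gene_class, self.pre_wgd_counts,
                              self.zr_count, post)


@dataclass(frozen=True)
class AncestralCall:
    pair_id: str
    state: str
    outgroup_with: int
    outgroup_without: int
    zr_has: bool | None
    post_wgd_species_with: int
    post_wgd_species_total: int


@dataclass(frozen=True)
class PairEvent:
    """Loss/gain bookkeeping for one pair; losses is None when undefined."""
    pair_id: str
    losses: int | None
    gains_a: bool = False
    gains_b: bool = False
    missing_sc: bool = False


@dataclass(frozen=True)
class GainCall:
    gains_a: bool
    gains_b: bool
    ambiguous: bool = False


@dataclass(frozen=True)
class EnrichmentResult:
    rpg_losses: int
    nonrpg_losses: int
    rpg_pairs_at_risk: int
    nonrpg_pairs_at_risk: int
    null_p: float
    p_value: float


def _pair_has_intron(pair: tuple[int | None, int | None]) -> bool:
    return any(v is not None and v >= 1 for v in pair)


def _majority(n_with: int, n_without: int) -> bool | None:
    """Strict majority; None marks an exact tie (including 0 vs 0)."""
    if n_with > n_without:
        return True
    if n_with < n_without:
        return False
    return None


def infer_ancestral_state(record: OrthologRecord,
                          include_self: bool = True) -> AncestralCall:
    """Majority-rule call of intron presence in the pre-WGD ancestor.

    ``include_self=False`` drops S. cerevisiae from the post-WGD majority
    when inferring the ancestor of its own pair.
    """
    og = [v for v in (record.pre_wgd_counts.get(s) for s in PRE_WGD_SPECIES)
          if v is not None]
    og_with = sum(1 for v in og if v >= 1)
    og_without = len(og) - og_with

    post_species = [s for s in POST_WGD_SPECIES
                    if include_self or s != "Sc"]
    post = [p for p in (record.post_wgd_counts.get(s) for s in post_species)
            if p is not None]
    post_with = sum(1 for p in post if _pair_has_intron(p))
    post_total = len(post)

    zr_has = None if record.zr_count is None else record.zr_count >= 1

    og_major = _majority(og_with, og_without)
    if og_major is None:
        state = AMBIGUOUS
    elif not og_major:
        state = ABSENT
    elif zr_has:
        state = PRESENT
    else:
        post_major = _majority(post_with, post_total - post_with)
        if post_major is None:
            state = AMBIGUOUS
        else:
            state = PRESENT if post_major else ABSENT

    return AncestralCall(record.pair_id, state, og_with, og_without,
                         zr_has, post_with, post_total)


def count_pair_losses(record: OrthologRecord, call: AncestralCall) -> PairEvent:
    """Losses in the S. cerevisiae lineage: one per intronless copy.

    Defined only when the ancestor was called PRESENT; a missing
    S. cerevisiae pair yields losses=None with the missing flag set.
    """
    if call.state != PRESENT:
        return PairEvent(record.pair_id, losses=None)
    sc = record.sc_counts
    if sc is None or any(v is None for v in sc):
        return PairEvent(record.pair_id, losses=None, missing_sc=True)
    losses = sum(1 for v in sc if v == 0)
    return PairEvent(record.pair_id, losses=losses)


def infer_gain(record: OrthologRecord, call: AncestralCall) -> GainCall:
    """Flag S. cerevisiae intron gains.

    A copy with an intron is a candidate gain when the ancestor was ABSENT
    and a strict majority of the other non-missing post-WGD species lack
    introns in both copies.  A tie in that majority blocks the call.
    """
    if call.state != ABSENT:
        return GainCall(False, False)
    sc = record.sc_counts
    if sc is None:
        return GainCall(False, False)
    others = [p for p in (record.post_wgd_counts.get(s)
                          for s in POST_WGD_SPECIES if s != "Sc")
              if p is not None]
    n_without = sum(1 for p in others if not _pair_has_intron(p))
    major = _majority(n_without, len(others) - n_without)
    if major is None:
        return GainCall(False, False, ambiguous=True)
    if not major:
        return GainCall(False, False)
    a, b = sc
    return GainCall(a is not None and a >= 1, b is not None and b >= 1)


def simple_differential_count(record: OrthologRecord) -> bool | None:
    """True when the two S. cerevisiae copies differ in intron count.

    The crude loss proxy that ignores double losses: a pair with unequal
    counts has lost at least one intron.  None if either copy is missing.
    """
    sc = record.sc_counts
    if sc is None or any(v is None for v in sc):
        return None
    return sc[0] != sc[1]


def loss_enrichment_test(events: Sequence[PairEvent],
                         classes: Mapping[str, str]) -> EnrichmentResult:
    """Lower-tail exact binomial test for a deficit of RPG intron losses.

    Each loss event (a two-loss pair contributes two) is a Bernoulli trial
    landing on an RPG pair with null probability equal to the RPG fraction
    of at-risk pairs (those with an inferred intron-containing ancestor).
    Small p says RPGs lost fewer introns than their at-risk share predicts.
    """
    at_risk = [e for e in events if e.losses is not None]
    rpg_at_risk = sum(1 for e in at_risk if classes[e.pair_id] == "RPG")
    nonrpg_at_risk = len(at_risk) - rpg_at_risk
    if len(at_risk) == 0:
        raise ValueError("no at-risk pairs (no PRESENT ancestral calls)")
    rpg_losses = sum(e.losses for e in at_risk
                     if classes[e.pair_id] == "RPG")
    nonrpg_losses = sum(e.losses for e in at_risk
                        if classes[e.pair_id] != "RPG")
    n = rpg_losses + nonrpg_losses
    if n == 0:
        raise ValueError("no loss events to test")
    null_p = rpg_at_risk / len(at_risk)
    p_value = float(stats.binom.cdf(rpg_losses, n, null_p))
    return EnrichmentResult(rpg_losses, nonrpg_losses, rpg_at_risk,
                            nonrpg_at_risk, null_p, p_value)


def summarize_matrix(records: Sequence[OrthologRecord],
                     calls: Sequence[AncestralCall],
                     events: Sequence[PairEvent],
                     ) -> tuple[pd.DataFrame, dict[str, dict[int, int]]]:
    """Species-by-pair intron matrix plus per-class loss histograms."""
    calls_by = {c.pair_id: c for c in calls}
    events_by = {e.pair_id: e for e in events}
    rows = []
    hist: dict[str, dict[int, int]] = {"RPG": {0: 0, 1: 0, 2: 0},
                                       "non-RPG": {0: 0, 1: 0, 2: 0}}
    for rec in records:
        call = calls_by[rec.pair_id]
        ev = events_by[rec.pair_id]
        row: dict = {"pair_id": rec.pair_id, "gene_a": rec.gene_a,
                     "gene_b": rec.gene_b, "gene_class": rec.gene_class}
        for s in PRE_WGD_SPECIES:
            row[s] = rec.pre_wgd_counts.get(s)
        row["Zr"] = rec.zr_count
        for s in POST_WGD_SPECIES:
            p = rec.post_wgd_counts.get(s)
            row[s] = None if p is None else "|".join(
                "NA" if v is None else str(v) for v in p)
        row["ancestral_state"] = call.state
        row["losses"] = ev.losses
        rows.append(row)
        if ev.losses is not None:
            hist[rec.gene_class][ev.losses] += 1
    return pd.DataFrame(rows), hist


def analyze_pairs(records: Sequence[OrthologRecord],
                  include_self: bool = True,
                  ) -> tuple[list[AncestralCall], list[PairEvent],
                             EnrichmentResult | None]:
    """Full inference chain: ancestral calls, loss/gain events, class test.

    The enrichment result is None when no loss events exist to test.
    """
    calls, events = [], []
    for rec in records:
        call = infer_ancestral_state(rec, include_self=include_self)
        ev = count_pair_losses(rec, call)
        gain = infer_gain(rec, call)
        events.append(PairEvent(ev.pair_id, ev.losses, gain.gains_a,
                                gain.gains_b, ev.missing_sc))
        calls.append(call)
    classes = {rec.pair_id: rec.gene_class for rec in records}
    total_losses = sum(e.losses for e in events if e.losses is not None)
    enrichment = (loss_enrichment_test(events, classes)
                  if total_losses > 0 else None)
    return calls, events, enrichment


# ---------------------------------------------------------------------------
# TSV interchange: one row per pair, "NA" for missing, "x|y" per-copy counts.

def _parse_count(tok: str) -> int | None:
    return None if tok == "NA" else int(tok)


def _parse_pair(tok: str) -> tuple[int | None, int | None] | None:
    if tok == "NA":
        return None
    a, b = tok.split("|")
    return (_parse_count(a), _parse_count(b))


def read_ortholog_table(path) -> list[OrthologRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for _, r in df.iterrows():
        records.append(OrthologRecord(
            pair_id=r["pair_id"], gene_a=r["gene_a"], gene_b=r["gene_b"],
            gene_class=r["gene_class"],
            pre_wgd_counts={s: _parse_count(r[s]) for s in PRE_WGD_SPECIES},
            zr_count=_parse_count(r["Zr"]),
            post_wgd_counts={s: _parse_pair(r[s]) for s in POST_WGD_SPECIES},
        ))
    return records


def write_ortholog_table(records: Iterable[OrthologRecord], path) -> None:
    rows = []
    for rec in records:
        row = {"pair_id": rec.pair_id, "gene_a": rec.gene_a,
               "gene_b": rec.gene_b, "gene_class": rec.gene_class}
        for s in PRE_WGD_SPECIES:
            v = rec.pre_wgd_counts.get(s)
            row[s] = "NA" if v is None else str(v)
        row["Zr"] = "NA" if rec.zr_count is None else str(rec.zr_count)
        for s in POST_WGD_SPECIES:
            p = rec.post_wgd_counts.get(s)
            row[s] = "NA" if p is None else "|".join(
                "NA" if v is None else str(v) for v in p)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
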