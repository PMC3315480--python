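"""Synthetic inputs with the statistical structure each pipeline stage assumes.

Four generators, all deterministic given their seed:

* ``simulate_intron_evolution`` — ortholog intron-count matrices for
  WGD-derived gene pairs, with class-specific per-lineage loss rates and
  missing entries, plus the ground-truth ancestral states and loss counts.
* ``generate_intron_sequences`` — complete intron sequences that either
  conform to the splice-site grammar or break exactly one named criterion.
* ``simulate_spliced_ests`` — BED12-style spliced alignments over a
  two-intron gene template whose minor isoform uses an alternative 5'
  splice site introducing a premature termination codon.
* ``simulate_feedback_expression`` — splicing-sensitive probe tables and
  qPCR Cq tables for intron-deletion mutants of a cross-regulating gene
  pair: the deleted copy derepresses, the paralog compensates by splicing
  inhibition (intron accumulation), and the double mutant derepresses both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .est import GeneModel, SplicedAlignment
from .grammar import BRANCHPOINTS, FIVE_SS
from .wgd import POST_WGD_SPECIES, PRE_WGD_SPECIES, OrthologRecord

#: intron-probe log2 change reported for a deleted intron (signal floor)
DELETED_INTRON_LOG2 = -5.0

#: floor on a compensating paralog's fold-change (a >16-fold collapse is
#: reported as 16-fold; transcript pools never go negative)
MIN_COMPENSATED_FOLD = 2.0 ** -4


# ---------------------------------------------------------------------------
# 1. intron evolution across the WGD

@dataclass(frozen=True)
class EvolutionSimConfig:
    """Defaults emulate the study scale: 95 pairs descended from an
    intron-containing pre-WGD ancestor, roughly half ribosomal protein
    genes, no RPG losses and ~25% per-copy loss probability elsewhere."""
    n_pairs: int = 95
    rpg_fraction: float = 0.48
    ancestor_intron_prob: float = 1.0
    loss_prob_rpg: float = 0.0
    loss_prob_nonrpg: float = 0.25
    missing_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rpg_fraction", "ancestor_intron_prob",
                     "loss_prob_rpg", "loss_prob_nonrpg", "missing_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def simulate_intron_evolution(config: EvolutionSimConfig,
                              ) -> tuple[list[OrthologRecord], pd.DataFrame]:
    """Draw ortholog intron matrices plus a ground-truth table.

    Each pair draws an ancestral intron state; every descendant lineage
    (six outgroups, Z. rouxii, and two copies in each post-WGD species)
    independently loses the intron with its class's per-copy probability.
    A loss collapses the copy's count to 0.  Entries are then masked
    missing at ``missing_prob`` (the S. cerevisiae pair is never masked so
    loss counts stay observable).  Truth records the ancestral state and
    the S. cerevisiae loss count.
    """
    rng = np.random.default_rng(config.seed)
    records, truth_rows = [], []
    for i in range(config.n_pairs):
        is_rpg = rng.random() < config.rpg_fraction
        gene_class = "RPG" if is_rpg else "non-RPG"
        loss_p = config.loss_prob_rpg if is_rpg else config.loss_prob_nonrpg
        ancestor = rng.random() < config.ancestor_intron_prob

        def descend() -> int:
            if not ancestor:
                return 0
            return 0 if rng.random() < loss_p else 1

        pre = {s: descend() for s in PRE_WGD_SPECIES}
        zr = descend()
        post = {s: (descend(), descend()) for s in POST_WGD_SPECIES}
        sc = post["Sc"]
        true_losses = sum(1 for v in sc if v == 0) if ancestor else None

        pre_masked = {s: (None if rng.random() < config.missing_prob else v)
                      for s, v in pre.items()}
        zr_masked = None if rng.random() < config.missing_prob else zr
        post_masked: dict = {}
        for s, pair in post.items():
            if s != "Sc" and rng.random() < config.missing_prob:
                post_masked[s] = None
            else:
                post_masked[s] = pair

        pair_id = f"pair{i:04d}"
        records.append(OrthologRecord(
            pair_id=pair_id, gene_a=f"{pair_id}a", gene_b=f"{pair_id}b",
            gene_class=gene_class, pre_wgd_counts=pre_masked,
            zr_count=zr_masked, post_wgd_counts=post_masked))
        truth_rows.append({"pair_id": pair_id, "gene_class": gene_class,
                           "ancestor_intron": ancestor,
                           "sc_losses": true_losses})
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# 2. grammar-conformant and grammar-violating intron sequences

#: spacer alphabets chosen so fillers can never spell a donor, branchpoint
#: or premature [tca]ag acceptor (all of those need an 'a')
_S1_ALPHABET = np.array(list("cgt"))
_S2_ALPHABET = np.array(list("cgt"))
THREE_SS = ("tag", "cag", "aag")

VIOLATION_KINDS = ("five_ss", "s1_short", "branchpoint", "s2_long",
                   "three_ss")


def _build_intron(rng: np.random.Generator, violation: str | None) -> str:
    five = str(rng.choice(FIVE_SS))
    bp = str(rng.choice(BRANCHPOINTS))
    three = str(rng.choice(THREE_SS))
    s1_len = int(rng.integers(30, 121))
    s2_len = int(rng.integers(1, 51))
    if violation == "five_ss":
        five = "gtcagt"
    elif violation == "s1_short":
        s1_len = 29
    elif violation == "branchpoint":
        bp = "tcttaac"
    elif violation == "s2_long":
        s2_len = 51
    elif violation == "three_ss":
        three = "gag"
    s1 = "".join(rng.choice(_S1_ALPHABET, size=s1_len))
    s2 = "".join(rng.choice(_S2_ALPHABET, size=s2_len))
    return five + s1 + bp + s2 + three


def generate_intron_sequences(n_conformant: int, n_violating: int,
                              seed: int = 0) -> list[tuple[str, str]]:
    """Labelled intron sequences: ("conformant", seq) or the broken rule.

    Conformant sequences sample uniformly over the grammar's donor,
    branchpoint and acceptor sets with spacer lengths in [30, 120] and
    [1, 50]; violating sequences break exactly one named criterion.
    Spacers avoid 'a' so no accidental secondary signal can rescue or
    shorten a match.
    """
    rng = np.random.default_rng(seed)
    out = [(_build_intron(rng, None), "conformant")
           for _ in range(n_conformant)]
    for i in range(n_violating):
        kind = VIOLATION_KINDS[i % len(VIOLATION_KINDS)]
        out.append((_build_intron(rng, kind), kind))
    return out


# ---------------------------------------------------------------------------
# 3. spliced ESTs over an alternatively-spliced gene template

@dataclass(frozen=True)
class ESTSimConfig:
    n_ests: int = 1000
    minor_isoform_freq: float = 0.03
    est_len_min: int = 150
    est_len_max: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.minor_isoform_freq <= 1.0:
            raise ValueError("minor_isoform_freq must be in [0, 1]")
        if not 0 < self.est_len_min <= self.est_len_max:
            raise ValueError("invalid EST length range")


def build_template_locus() -> tuple[dict[str, str], GeneModel,
                                    tuple[tuple[int, int], ...],
                                    tuple[tuple[int, int], ...]]:
    """A deterministic three-exon gene with a PTC+ alternative 5'SS isoform.

    Plus strand on a 1 kb chromosome "chrT".  The canonical isoform has
    exons (100,250), (350,550), (700,900) with CDS [130, 821) and GT..AG
    introns of 100 and 150 nt.  The minor isoform extends exon 2 by 60 nt
    into intron 2 via an alternative donor at 610; the extension carries an
    in-frame stop ("taa" at 551) more than 50 nt upstream of the isoform's
    last junction, so the PTC is a predicted NMD substrate.

    Returns (genome, model, canonical_exons, minor_exons).
    """
    seq = ["c"] * 1000
    def put(pos: int, s: str) -> None:
        seq[pos:pos + len(s)] = list(s)

    put(100, "cct" * 10)                       # 5' UTR
    put(130, "atg" + "gct" * 39)               # CDS in exon 1
    put(250, "gt" + "c" * 96 + "ag")           # intron 1
    put(350, "gct" * 66 + "cc")                # CDS in exon 2
    # intron 2: canonical donor at 550; the first 60 nt double as the
    # minor isoform's exon extension and carry the PTC ("taa" at 551);
    # minor donor at 610; shared acceptor at 698
    put(550, "gtaa" + "c" * 56 + "gt" + "c" * 86 + "ag")
    put(700, "g" + "gct" * 39 + "taa" + "c" * 79)   # CDS end + 3' UTR
    genome = {"chrT": "".join(seq)}

    model = GeneModel("RPS9-like", "chrT", "+",
                      ((100, 250), (350, 550), (700, 900)), 130, 821)
    canonical = ((100, 250), (350, 550), (700, 900))
    minor = ((100, 250), (350, 610), (700, 900))
    return genome, model, canonical, minor


def _transcript_to_blocks(exons: Sequence[tuple[int, int]],
                          a: int, b: int) -> tuple[tuple[int, int], ...]:
    """Map a transcript-coordinate window [a, b) onto genomic blocks."""
    blocks, t = [], 0
    for s, e in exons:
        length = e - s
        lo, hi = max(a, t), min(b, t + length)
        if lo < hi:
            blocks.append((s + lo - t, s + hi - t))
        t += length
    return tuple(blocks)


def simulate_spliced_ests(config: ESTSimConfig,
                          ) -> tuple[dict[str, str], GeneModel,
                                     list[SplicedAlignment], dict]:
    """Sample ESTs over the template gene, a few from the PTC+ isoform.

    Each EST picks an isoform (minor with probability
    ``minor_isoform_freq``), a length, and a uniform start over the
    spliced transcript, then maps back to genomic blocks; gaps therefore
    correspond to spliced-out introns with GT/AG flanks baked into the
    template genome.  Truth records the isoform of every EST and the two
    competing junctions of intron 2.
    """
    genome, model, canonical, minor = build_template_locus()
    rng = np.random.default_rng(config.seed)
    isoforms = {"canonical": canonical, "minor": minor}
    lengths = {k: sum(e - s for s, e in ex) for k, ex in isoforms.items()}
    alignments, labels = [], []
    for i in range(config.n_ests):
        label = ("minor" if rng.random() < config.minor_isoform_freq
                 else "canonical")
        exons = isoforms[label]
        tlen = lengths[label]
        est_len = int(rng.integers(config.est_len_min,
                                   min(config.est_len_max, tlen) + 1))
        a = int(rng.integers(0, tlen - est_len + 1))
        blocks = _transcript_to_blocks(exons, a, a + est_len)
        alignments.append(SplicedAlignment(f"est{i:05d}", model.chrom,
                                           model.strand, blocks))
        labels.append(label)
    truth = {
        "labels": labels,
        "n_minor": labels.count("minor"),
        "canonical_junction": (550, 700),
        "minor_junction": (610, 700),
        "minor_exons": minor,
        "canonical_exons": canonical,
    }
    return genome, model, alignments, truth


# ---------------------------------------------------------------------------
# 4. cross-regulatory expression feedback

@dataclass(frozen=True)
class FeedbackSimConfig:
    """Defaults emulate the measured S9 circuit: copy shares 6%/94% of the
    transcript pool, derepression folds 4.2 (minor copy) and 1.55 (major
    copy) so the fully derepressed double mutant totals ~171% of
    wild-type, and full transcript-level compensation by the paralog."""
    shares: tuple[float, float] = (6.0, 94.0)
    feedback_strength: float = 1.0
    derepression_fold_a: float = 4.2
    derepression_fold_b: float = 1.55
    noise_sd: float = 0.1
    n_replicates: int = 3
    n_background: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.shares) - 100.0) > 1e-9:
            raise ValueError("shares must sum to 100")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates")


def compensated_fold(p_mut: float, p_other: float, derepression_fold: float,
                     feedback_strength: float) -> float:
    """Paralog fold-change under transcript-level compensation.

    With feedback_strength = 1 the paralog absorbs the derepressed copy's
    transcript surplus one-for-one: fold = 1 - p_mut*(f-1)/p_other,
    floored at 1/16 (a pool cannot go negative; a collapse beyond 16-fold
    is reported at the floor).
    """
    fold = 1.0 - feedback_strength * p_mut * (derepression_fold - 1.0) / p_other
    return max(fold, MIN_COMPENSATED_FOLD)


def expected_log2_changes(config: FeedbackSimConfig) -> dict:
    """Noise-free per-gene log2 changes for each mutant, plus linear folds."""
    pa, pb = config.shares
    fa, fb = config.derepression_fold_a, config.derepression_fold_b
    fs = config.feedback_strength
    comp_b = compensated_fold(pa, pb, fa, fs)   # B's response in di_a
    comp_a = compensated_fold(pb, pa, fb, fs)   # A's response in di_b
    out = {}
    for mutant, fold_a, fold_b, deleted in (
            ("rps9a_di", fa, comp_b, ("A",)),
            ("rps9b_di", comp_a, fb, ("B",)),
            ("rps9ab_di", fa, fb, ("A", "B"))):
        genes = {}
        for gene, fold, tag in (("RPS9A", fold_a, "A"),
                                ("RPS9B", fold_b, "B")):
            exon = float(np.log2(fold))
            if tag in deleted:
                intron = DELETED_INTRON_LOG2
            else:
                # feedback acts by splicing inhibition: pre-mRNA piles up
                intron = exon + fs
            genes[gene] = {"exon": exon, "junction": exon, "intron": intron,
                           "fold": fold}
        out[mutant] = genes
    return out


def simulate_feedback_expression(config: FeedbackSimConfig) -> dict:
    """Probe tables and qPCR tables for the cross-regulation experiment.

    Returns a dict with:
      probe_table    — gene_id, mutant_id, probe_class, replicate, log2_ratio
      qpcr_table     — primer, sample, bio_rep, tech_rep, Cq
      dilution_table — primer, amount_ng, Cq  (a perfect-efficiency series)
      truth          — the noise-free expected changes and folds
    """
    rng = np.random.default_rng(config.seed)
    truth = expected_log2_changes(config)

    probe_rows = []
    mutants = list(truth)
    for mutant in mutants:
        for gene, chans in truth[mutant].items():
            for cls in ("intron", "junction", "exon"):
                for rep in range(config.n_replicates):
                    probe_rows.append({
                        "gene_id": gene, "mutant_id": mutant,
                        "probe_class": cls, "replicate": rep,
                        "log2_ratio": chans[cls]
                        + rng.normal(0.0, config.noise_sd)})
        for g in range(config.n_background):
            for cls in ("intron", "junction", "exon"):
                for rep in range(config.n_replicates):
                    probe_rows.append({
                        "gene_id": f"GENE{g:04d}", "mutant_id": mutant,
                        "probe_class": cls, "replicate": rep,
                        "log2_ratio": rng.normal(0.0, config.noise_sd)})
    probe_table = pd.DataFrame(probe_rows)

    # qPCR: perfect-doubling chemistry; Cq = intercept + slope*log10(Q)
    slope = -1.0 / np.log10(2.0)
    intercepts = {"RPS9A": 15.0, "RPS9B": 12.0, "SCR1": 14.0}
    base_quantity = {"RPS9A": config.shares[0], "RPS9B": config.shares[1],
                     "SCR1": 50.0}
    dil_rows = []
    for primer, b in intercepts.items():
        for amount in (100.0, 20.0, 4.0, 0.8, 0.16):
            dil_rows.append({"primer": primer, "amount_ng": amount,
                             "Cq": b + slope * np.log10(amount)})
    dilution_table = pd.DataFrame(dil_rows)

    qpcr_rows = []
    samples = {"wt": {"RPS9A": 1.0, "RPS9B": 1.0}}
    for mutant in mutants:
        samples[mutant] = {g: truth[mutant][g]["fold"]
                           for g in ("RPS9A", "RPS9B")}
    for sample, folds in samples.items():
        for bio in range(config.n_replicates):
            bio_noise = {p: rng.normal(0.0, config.noise_sd)
                         for p in intercepts}
            for primer in intercepts:
                fold = folds.get(primer, 1.0)
                q = base_quantity[primer] * fold * 2.0 ** bio_noise[primer]
                cq = intercepts[primer] + slope * np.log10(q)
                for tech in range(3):
                    qpcr_rows.append({"primer": primer, "sample": sample,
                                      "bio_rep": bio, "tech_rep": tech,
                                      "Cq": cq})
    qpcr_table = pd.DataFrame(qpcr_rows)

    return {"probe_table": probe_table, "qpcr_table": qpcr_table,
            "dilution_table": dilution_table, "truth": truth,
            "config": config}
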