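"""Evaluation of deletion calls against a simulated truth set.

Truth deletions are grouped into *loci* -- connected components of reference
overlap -- so a locus holds either one deletion (single) or a set of
overlapping ones (pair, or multi for three and more).  A reported cluster
matches a truth deletion when it has enough support, its breakpoint bounds
contain the deletion (``l <= start`` and ``end <= r``) and its size estimate
agrees within three standard deviations (``|size - mu| <= 3 sigma``).  Each
supported cluster is assigned to at most one locus; supported clusters that
match nothing but overlap a locus are assigned positionally, and those at
truth-free positions form "none"-truth loci (false calls).

Per-locus classifications feed the detection-rate summary::

    TPR1 = #(single predicted as single) / #simulated singles
    FPR1 = #(single predicted elsewhere) / (#simulated pairs + #false loci)
    TPR2 = #(pair predicted as pair)     / #simulated pairs
    FPR2 = #(pair predicted elsewhere)   / (#simulated singles + #false loci)

plus the mapping mis-assignment rate over correctly resolved pairs: the
fraction of member mappings placed in the cluster that does not match their
haplotype-of-origin deletion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .report import ClusterRecord
from .simulate import MappingTruth, TruthDeletion

KIND_NONE = "none"
KIND_SINGLE = "single"
KIND_PAIR = "pair"
KIND_MULTI = "multi"


@dataclass(frozen=True)
class TruthLocus:
    locus_id: str
    chrom: str
    start: int
    end: int
    deletions: tuple[TruthDeletion, ...]

    @property
    def kind(self) -> str:
        n = len(self.deletions)
        return (KIND_NONE, KIND_SINGLE, KIND_PAIR)[n] if n <= 2 else KIND_MULTI


@dataclass
class LocusClassification:
    locus_id: str
    chrom: str
    truth_kind: str
    predicted_kind: str
    matched_cluster_ids: tuple[str, ...]
    #: cluster_id -> deletion_id it matched (None for positional assignment)
    cluster_deletion: dict[str, str | None]
    truth_deletion_ids: tuple[str, ...]


@dataclass(frozen=True)
class RateSummary:
    """Detection rates; ``nan`` marks an undefined rate (zero denominator)."""

    tpr1: float
    fpr1: float
    tpr2: float
    fpr2: float
    misassignment_rate: float


def truth_loci(truth: Sequence[TruthDeletion]) -> list[TruthLocus]:
    """Connected components of reference overlap among truth deletions."""
    loci: list[TruthLocus] = []
    by_chrom: dict[str, list[TruthDeletion]] = {}
    for d in truth:
        by_chrom.setdefault(d.chrom, []).append(d)
    idx = 0
    for chrom in sorted(by_chrom):
        dels = sorted(by_chrom[chrom], key=lambda d: (d.start, d.end))
        group: list[TruthDeletion] = []
        group_end = None
        for d in dels:
            if group_end is not None and d.start < group_end:
                group.append(d)
                group_end = max(group_end, d.end)
            else:
                if group:
                    loci.append(_locus(idx, chrom, group))
                    idx += 1
                group = [d]
                group_end = d.end
        if group:
            loci.append(_locus(idx, chrom, group))
            idx += 1
    return loci


def _locus(idx: int, chrom: str, dels: list[TruthDeletion]) -> TruthLocus:
    return TruthLocus(
        locus_id=f"L{idx}",
        chrom=chrom,
        start=min(d.start for d in dels),
        end=max(d.end for d in dels),
        deletions=tuple(dels),
    )


def _matches(c: ClusterRecord, d: TruthDeletion) -> bool:
    return (
        c.chrom == d.chrom
        and c.l <= d.start
        and d.end <= c.r
        and abs(d.size - c.mu) <= 3.0 * c.sigma
    )


def classify_loci(
    clusters: Sequence[ClusterRecord],
    truth: Sequence[TruthDeletion],
    min_support: int = 2,
) -> list[LocusClassification]:
    """Classify every truth locus (and every false-call locus) by the number
    of distinct supported clusters assigned to it."""
    loci = truth_loci(truth)
    locus_of_del = {
        d.deletion_id: locus for locus in loci for d in locus.deletions
    }
    assigned: dict[str, list[tuple[ClusterRecord, str | None]]] = {
        locus.locus_id: [] for locus in loci
    }
    unplaced: list[ClusterRecord] = []

    for c in clusters:
        if c.n < min_support:
            continue
        matched = [d for d in truth if _matches(c, d)]
        if matched:
            # assign to the locus holding most matched deletions
            votes: dict[str, int] = {}
            for d in matched:
                votes[locus_of_del[d.deletion_id].locus_id] = (
                    votes.get(locus_of_del[d.deletion_id].locus_id, 0) + 1
                )
            locus_id = min(votes, key=lambda k: (-votes[k], k))
            in_locus = [
                d for d in matched
                if locus_of_del[d.deletion_id].locus_id == locus_id
            ]
            best = min(in_locus, key=lambda d: abs(d.size - c.mu))
            assigned[locus_id].append((c, best.deletion_id))
            continue
        # no size-consistent match: fall back to positional overlap
        best_locus, best_ov = None, 0
        for locus in loci:
            if locus.chrom != c.chrom:
                continue
            ov = min(c.r, locus.end) - max(c.l, locus.start)
            if ov > best_ov:
                best_locus, best_ov = locus, ov
        if best_locus is not None:
            assigned[best_locus.locus_id].append((c, None))
        else:
            unplaced.append(c)

    out: list[LocusClassification] = []
    for locus in loci:
        entries = assigned[locus.locus_id]
        out.append(
            LocusClassification(
                locus_id=locus.locus_id,
                chrom=locus.chrom,
                truth_kind=locus.kind,
                predicted_kind=_kind(len(entries)),
                matched_cluster_ids=tuple(c.cluster_id for c, _ in entries),
                cluster_deletion={c.cluster_id: d for c, d in entries},
                truth_deletion_ids=tuple(
                    d.deletion_id for d in locus.deletions
                ),
            )
        )
    # group remaining false calls into loci by mutual [l, r) overlap
    for i, group in enumerate(_overlap_groups(unplaced)):
        out.append(
            LocusClassification(
                locus_id=f"F{i}",
                chrom=group[0].chrom,
                truth_kind=KIND_NONE,
                predicted_kind=_kind(len(group)),
                matched_cluster_ids=tuple(c.cluster_id for c in group),
                cluster_deletion={c.cluster_id: None for c in group},
                truth_deletion_ids=(),
            )
        )
    return out


def _kind(n: int) -> str:
    return (KIND_NONE, KIND_SINGLE, KIND_PAIR)[n] if n <= 2 else KIND_MULTI


def _overlap_groups(
    clusters: Iterable[ClusterRecord],
) -> list[list[ClusterRecord]]:
    groups: list[list[ClusterRecord]] = []
    by_chrom: dict[str, list[ClusterRecord]] = {}
    for c in clusters:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom in sorted(by_chrom):
        cs = sorted(by_chrom[chrom], key=lambda c: (c.l, c.r))
        cur: list[ClusterRecord] = []
        cur_end = None
        for c in cs:
            if cur_end is not None and c.l < cur_end:
                cur.append(c)
                cur_end = max(cur_end, c.r)
            else:
                if cur:
                    groups.append(cur)
                cur = [c]
                cur_end = c.r
        if cur:
            groups.append(cur)
    return groups


def compute_rates(
    classifications: Sequence[LocusClassification],
    mapping_truth: dict[str, MappingTruth],
    clusters: Sequence[ClusterRecord],
) -> RateSummary:
    """Detection and mis-assignment rates from per-locus classifications."""
    n_single = sum(c.truth_kind == KIND_SINGLE for c in classifications)
    n_pair = sum(c.truth_kind == KIND_PAIR for c in classifications)
    n_false_loci = sum(
        c.truth_kind == KIND_NONE and c.predicted_kind != KIND_NONE
        for c in classifications
    )
    tp1 = sum(
        c.truth_kind == KIND_SINGLE and c.predicted_kind == KIND_SINGLE
        for c in classifications
    )
    tp2 = sum(
        c.truth_kind == KIND_PAIR and c.predicted_kind == KIND_PAIR
        for c in classifications
    )
    fp1 = sum(
        c.truth_kind != KIND_SINGLE and c.predicted_kind == KIND_SINGLE
        for c in classifications
    )
    fp2 = sum(
        c.truth_kind != KIND_PAIR and c.predicted_kind == KIND_PAIR
        for c in classifications
    )

    def rate(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    mis, total = _misassignment_counts(classifications, mapping_truth, clusters)
    return RateSummary(
        tpr1=rate(tp1, n_single),
        fpr1=rate(fp1, n_pair + n_false_loci),
        tpr2=rate(tp2, n_pair),
        fpr2=rate(fp2, n_single + n_false_loci),
        misassignment_rate=rate(mis, total) if total else math.nan,
    )


def _misassignment_counts(
    classifications: Sequence[LocusClassification],
    mapping_truth: dict[str, MappingTruth],
    clusters: Sequence[ClusterRecord],
) -> tuple[int, int]:
    """Over correctly resolved pairs (both partners matched by distinct
    clusters), count member mappings whose haplotype-of-origin deletion is
    not the one their cluster matched.  Mappings without a truth annotation
    (noise) are excluded."""
    by_id = {c.cluster_id: c for c in clusters}
    mis = 0
    total = 0
    for cl in classifications:
        if cl.truth_kind != KIND_PAIR or cl.predicted_kind != KIND_PAIR:
            continue
        matched = [d for d in cl.cluster_deletion.values() if d is not None]
        if len(set(matched)) != 2:
            continue
        for cid, did in cl.cluster_deletion.items():
            rec = by_id.get(cid)
            if rec is None or did is None:
                continue
            for mid in rec.members:
                ann = mapping_truth.get(mid)
                if ann is None:
                    continue
                origin_ids, _hap = ann
                total += 1
                if did not in origin_ids:
                    mis += 1
    return mis, total


def write_rates_tsv(rates: RateSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for name in ("tpr1", "fpr1", "tpr2", "fpr2", "misassignment_rate"):
            fh.write(f"{name}\t{getattr(rates, name)!r}\n")


def write_classifications_tsv(
    classifications: Sequence[LocusClassification], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tchrom\ttruth_kind\tpredicted_kind\t"
                 "matched_clusters\ttruth_deletions\n")
        for c in classifications:
            fh.write(
                f"{c.locus_id}\t{c.chrom}\t{c.truth_kind}\t"
                f"{c.predicted_kind}\t{','.join(c.matched_cluster_ids) or '.'}"
                f"\t{','.join(c.truth_deletion_ids) or '.'}\n"
            )
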