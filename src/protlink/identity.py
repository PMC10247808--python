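"""Proteome-only identity, relative detection, and mislabel diagnosis.

Three ways the linking machinery identifies people beyond the direct
proteome-to-genome match: (1) serial proteomes of the same subject are
mutually nearest in Euclidean protein space, so a proteome can be matched
to an earlier proteome without any genotypes; (2) a first-degree
relative's genome shares enough alleles to rank highly in the odds
ranking; (3) when subjects have proteomes from multiple visits, the
pattern of confident mismatches distinguishes a one-visit plasma swap
from a persistent DNA mislabel.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .containers import GenotypeMatrix, ProteomeMatrix
from .linker import LinkResult, NBModel, score_matrix, top_pct_window, _result_from_scores

__all__ = [
    "DiagnosedEvent",
    "SwapReport",
    "proteome_distance_match",
    "relative_detection",
    "link_visits",
    "diagnose_mismatches",
]

logger = logging.getLogger(__name__)


def proteome_distance_match(
    query: ProteomeMatrix,
    reference: ProteomeMatrix,
    proteins: Sequence[str] | None = None,
    standardize: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nearest-neighbour matching of proteomes to proteomes.

    Ranks reference rows by ascending Euclidean distance over the shared
    (or given) protein set, both matrices on the log scale.  With
    ``standardize`` each protein is z-scored using the reference mean and
    SD so high-variance proteins do not dominate the metric.

    Returns ``(assignment, distances)``: per query row the nearest
    reference id, its distance, and the rank of the same-id reference
    row when present; plus the full query x reference distance frame.
    """
    if query.transform_state != "log" or reference.transform_state != "log":
        raise ValueError("distance matching operates on log values")
    if proteins is None:
        shared = [p for p in query.proteins if p in set(reference.proteins)]
    else:
        shared = list(proteins)
        for p in shared:
            if p not in query.proteins or p not in reference.proteins:
                raise ValueError(f"protein {p!r} absent from one of the matrices")
    if not shared:
        raise ValueError("no shared proteins between query and reference")
    Q = query.values[shared].to_numpy(dtype=float)
    R = reference.values[shared].to_numpy(dtype=float)
    if standardize:
        mu = R.mean(axis=0)
        sd = R.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Q = (Q - mu) / sd
        R = (R - mu) / sd
    D = pd.DataFrame(cdist(Q, R), index=query.subjects, columns=reference.subjects)
    ref_ids = np.asarray(D.columns, dtype=object)
    rows = []
    for qid, dist in zip(D.index, D.to_numpy()):
        order = np.lexsort((ref_ids, dist))
        nearest = ref_ids[order[0]]
        rank_self = (
            int(np.nonzero(ref_ids[order] == qid)[0][0]) + 1
            if qid in reference.subjects
            else None
        )
        rows.append((qid, nearest, float(dist[order[0]]), rank_self))
    assign = pd.DataFrame(
        rows, columns=["query_id", "match_id", "distance", "rank_of_self"]
    ).set_index("query_id")
    return assign, D


def _sibling_sets(pedigree: pd.DataFrame) -> dict[str, set[str]]:
    sibs: dict[str, set[str]] = {}
    kids = pedigree[pedigree["father_id"].astype(str).str.len() > 0]
    for _, grp in kids.groupby(["father_id", "mother_id"]):
        ids = list(grp["subject_id"])
        for s in ids:
            sibs.setdefault(s, set()).update(x for x in ids if x != s)
    return sibs


def relative_detection(
    m: NBModel,
    proteomes: ProteomeMatrix,
    genomes: GenotypeMatrix,
    pedigree: pd.DataFrame,
    pct_mode: str = "ceil",
) -> tuple[pd.DataFrame, dict]:
    """Rank each subject's sibling genomes in their odds ranking.

    Subjects without a listed sibling in the genome set are excluded
    (logged).  Returns a per-subject table (best/worst sibling rank,
    flags) and a summary with the fraction of subjects having at least
    one sibling — and all siblings — inside the top 1% window.
    """
    sibs = _sibling_sets(pedigree)
    S = score_matrix(m, proteomes, genomes)
    genome_ids = np.asarray(S.columns, dtype=object)
    window = top_pct_window(len(genome_ids), mode=pct_mode)
    rows = []
    for pid, scores in zip(S.index, S.to_numpy()):
        present = [s for s in sorted(sibs.get(pid, ())) if s in genomes.subjects]
        if not present:
            logger.info("subject %r has no sibling genome; excluded", pid)
            continue
        order = np.lexsort((genome_ids, -scores))
        ranked = list(genome_ids[order])
        ranks = [ranked.index(s) + 1 for s in present]
        rows.append(
            {
                "subject_id": pid,
                "n_siblings": len(present),
                "best_sibling_rank": min(ranks),
                "worst_sibling_rank": max(ranks),
                "any_in_top1pct": min(ranks) <= window,
                "all_in_top1pct": max(ranks) <= window,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "subject_id", "n_siblings", "best_sibling_rank",
            "worst_sibling_rank", "any_in_top1pct", "all_in_top1pct",
        ],
    )
    n = len(table)
    summary = {
        "n_subjects": n,
        "window": window,
        "frac_any_sibling_top1pct": float(table["any_in_top1pct"].mean()) if n else np.nan,
        "frac_all_siblings_top1pct": float(table["all_in_top1pct"].mean()) if n else np.nan,
    }
    return table, summary


# ---------------------------------------------------------------------
# mislabel diagnosis
# ---------------------------------------------------------------------

@dataclasses.dataclass
class DiagnosedEvent:
    """One classified mislabel event with its supporting evidence."""

    kind: str  # plasma_swap | dna_mislabel | indeterminate
    subjects: tuple[str, ...]
    visits: tuple[str, ...]
    evidence: dict = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class SwapReport:
    """Classified mislabel events over a multi-visit cohort."""

    events: list[DiagnosedEvent]
    n_subjects: int = 0
    n_clean: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "kind": e.kind,
                    "subjects": ";".join(e.subjects),
                    "visits": ";".join(e.visits),
                    "evidence": ";".join(
                        f"{k}={v}" for k, v in sorted(e.evidence.items())
                    ),
                }
                for e in self.events
            ],
            columns=["kind", "subjects", "visits", "evidence"],
        )

    def summary(self) -> str:
        lines = [
            f"{self.n_subjects} subjects examined, {self.n_clean} clean, "
            f"{len(self.events)} event(s):"
        ]
        for e in self.events:
            where = f" at {','.join(e.visits)}" if e.visits else ""
            lines.append(f"  {e.kind}: {' <-> '.join(e.subjects)}{where}")
        return "\n".join(lines)


def link_visits(
    m: NBModel,
    proteomes_by_visit: Mapping[str, ProteomeMatrix],
    genomes: GenotypeMatrix,
) -> dict[str, dict[str, LinkResult]]:
    """Link every subject's proteome at every visit against all genomes."""
    out: dict[str, dict[str, LinkResult]] = {}
    for visit, pm in proteomes_by_visit.items():
        S = score_matrix(m, pm, genomes)
        genome_ids = np.asarray(S.columns, dtype=object)
        for pid, scores in zip(S.index, S.to_numpy()):
            res = _result_from_scores(pid, scores.copy(), genome_ids, None)
            out.setdefault(pid, {})[visit] = res
    return out


def diagnose_mismatches(
    results: Mapping[str, Mapping[str, LinkResult]],
    theta: float = 0.99,
) -> SwapReport:
    """Classify mismatching proteomes into swap/mislabel events.

    Only *confident* mismatches count as mislabel evidence: the top
    genome is not the subject's own AND its softmax posterior over the
    candidate set is at least ``theta``.  A low-confidence wrong top hit
    is a failed link, not evidence of a swap (mislabeled samples match
    the wrong genome with near-certain probability, while noise failures
    sit near the decision boundary).  Rules, per subject over their
    visit series:

    a. every visit confidently mismatches to the same wrong genome, and
       the subject has >= 2 visits -> DNA mislabel; when the implicated
       subject shows the mirror-image pattern the two are merged into a
       single reciprocal event;
    b. exactly one of >= 2 visits mismatches and a second subject shows
       the reciprocal confident mismatch at the same visit -> plasma swap;
    c. anything else (including any confident mismatch by a single-visit
       subject) -> indeterminate, with the evidence attached.
    """
    obs: dict[str, dict[str, tuple[str, float]]] = {}
    for sid, by_visit in results.items():
        obs[sid] = {v: (r.top_genome, r.top_posterior()) for v, r in by_visit.items()}

    mismatches: dict[str, dict[str, tuple[str, float]]] = {
        sid: {v: tp for v, tp in vis.items() if tp[0] != sid and tp[1] >= theta}
        for sid, vis in obs.items()
    }
    dirty = {sid for sid, mm in mismatches.items() if mm}
    events: list[DiagnosedEvent] = []
    handled: set[tuple[str, str]] = set()  # (subject, visit) pairs accounted for

    def _all_visits(sid: str) -> list[str]:
        return sorted(obs[sid])

    # rule (a): persistent confident mismatch to one genome
    dna_target: dict[str, str] = {}
    for sid in sorted(dirty):
        mm = mismatches[sid]
        if len(mm) != len(obs[sid]) or len(obs[sid]) < 2:
            continue
        targets = {t for t, _ in mm.values()}
        if len(targets) == 1 and all(post >= theta for _, post in mm.values()):
            dna_target[sid] = targets.pop()
    for sid in sorted(dna_target):
        if any((sid, v) in handled for v in obs[sid]):
            continue
        tgt = dna_target[sid]
        partners = (sid, tgt) if dna_target.get(tgt) == sid else (sid,)
        if len(partners) == 2:
            visits = tuple(sorted(set(_all_visits(sid)) | set(_all_visits(tgt))))
            covered = [(s, v) for s in partners for v in obs[s]]
        else:
            visits = tuple(_all_visits(sid))
            covered = [(sid, v) for v in obs[sid]]
        events.append(
            DiagnosedEvent(
                "dna_mislabel",
                tuple(sorted(set((sid, tgt)))),
                visits,
                {"matched_genome": tgt, "reciprocal": len(partners) == 2},
            )
        )
        handled.update(covered)

    # rule (b): single-visit reciprocal plasma swap
    for sid in sorted(dirty):
        mm = {v: tp for v, tp in mismatches[sid].items() if (sid, v) not in handled}
        if not mm:
            continue
        if len(mm) == 1 and len(obs[sid]) >= 2:
            (visit, (tgt, post)) = next(iter(mm.items()))
            partner = mismatches.get(tgt, {})
            recip = partner.get(visit)
            if (
                post >= theta
                and recip is not None
                and recip[0] == sid
                and recip[1] >= theta
                and (tgt, visit) not in handled
                and len(mismatches[tgt]) == 1
                and len(obs[tgt]) >= 2
            ):
                events.append(
                    DiagnosedEvent(
                        "plasma_swap",
                        tuple(sorted((sid, tgt))),
                        (visit,),
                        {"posterior_a": post, "posterior_b": recip[1]},
                    )
                )
                handled.add((sid, visit))
                handled.add((tgt, visit))

    # rule (c): everything left over
    for sid in sorted(dirty):
        left = {v: tp for v, tp in mismatches[sid].items() if (sid, v) not in handled}
        if not left:
            continue
        events.append(
            DiagnosedEvent(
                "indeterminate",
                (sid,),
                tuple(sorted(left)),
                {
                    f"{v}_top": tp[0] for v, tp in sorted(left.items())
                }
                | {f"{v}_posterior": round(tp[1], 6) for v, tp in sorted(left.items())},
            )
        )
        handled.update((sid, v) for v in left)

    return SwapReport(
        events=events,
        n_subjects=len(obs),
        n_clean=len(obs) - len(dirty),
    )
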