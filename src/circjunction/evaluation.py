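"""Scoring predictions against a truth set, and the RNase-R benchmark.

Sensitivity = TP/(TP+FN), precision = TP/(TP+FP) and the F1 score
2*sens*prec/(sens+prec) are computed from a greedy one-to-one matching of
predicted to true junctions.  On real data, where no truth list exists,
resistance to RNase R (an exonuclease that degrades linear RNA) serves as a
proxy: a candidate whose BSJ read count rises at least ``min_fold``-fold
after treatment is labelled a true positive, one that disappears or stays
flat a false positive, and the false-positive fraction of the assessed
candidates is the method's FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger("circjunction")


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    sensitivity: float
    precision: float
    f1: float


@dataclass
class RNaseRLabel:
    circ_id: str
    untreated_count: int
    treated_count: int
    label: str  # "TP", "FP" or "excluded"


def _metrics(tp: int, fp: int, fn: int) -> EvalResult:
    if tp + fn > 0:
        sens = tp / (tp + fn)
    else:
        logger.warning("sensitivity undefined (no truth entries); reporting 0")
        sens = 0.0
    if tp + fp > 0:
        prec = tp / (tp + fp)
    else:
        logger.warning("precision undefined (no predictions); reporting 0")
        prec = 0.0
    f1 = 2 * sens * prec / (sens + prec) if sens + prec > 0 else 0.0
    return EvalResult(tp, fp, fn, sens, prec, f1)


def match_predictions(
    predictions: list[tuple[str, int, int]],
    truth: list[tuple[str, int, int]],
    boundary_tol: int = 0,
) -> EvalResult:
    """Greedy one-to-one matching of predicted to true junctions.

    Junctions are ``(chrom, acceptor, donor)`` with 1-based inclusive
    coordinates.  A prediction matches an unmatched truth entry when the
    chromosomes agree and both boundaries lie within ``boundary_tol``;
    candidates are assigned in order of increasing total boundary distance.
    """
    matches = []
    for pi, (pc, pa, pd_) in enumerate(predictions):
        for ti, (tc, ta, td) in enumerate(truth):
            if pc == tc and abs(pa - ta) <= boundary_tol and abs(pd_ - td) <= boundary_tol:
                matches.append((abs(pa - ta) + abs(pd_ - td), pi, ti))
    matches.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    tp = 0
    for _, pi, ti in matches:
        if pi in used_p or ti in used_t:
            continue
        used_p.add(pi)
        used_t.add(ti)
        tp += 1
    return _metrics(tp, len(predictions) - tp, len(truth) - tp)


def rnase_r_assess(
    untreated: dict[str, int],
    treated: dict[str, int],
    min_bsj: int = 4,
    min_fold: float = 3.0,
) -> tuple[list[RNaseRLabel], float]:
    """Label candidates by RNase-R enrichment and compute the FDR.

    Candidates with fewer than ``min_bsj`` BSJ reads in the untreated
    sample are excluded from assessment; among the rest, a candidate is a
    TP iff its treated count reaches ``min_fold`` times the untreated count
    (inclusive).  FDR = FP / (TP + FP) over the assessed candidates.
    """
    labels: list[RNaseRLabel] = []
    tp = fp = 0
    for circ_id in sorted(untreated):
        u = untreated[circ_id]
        t = treated.get(circ_id, 0)
        if u < min_bsj:
            labels.append(RNaseRLabel(circ_id, u, t, "excluded"))
            continue
        if t >= min_fold * u:
            labels.append(RNaseRLabel(circ_id, u, t, "TP"))
            tp += 1
        else:
            labels.append(RNaseRLabel(circ_id, u, t, "FP"))
            fp += 1
    if tp + fp == 0:
        logger.warning("no assessable candidates; reporting FDR 0")
        return labels, 0.0
    return labels, fp / (tp + fp)


def read_junction_table(path: str) -> list[tuple[str, int, int]]:
    """Read a junction TSV with chrom/start/end columns (detector or truth output)."""
    df = pd.read_csv(path, sep="\t")
    return [(str(r.chrom), int(r.start), int(r.end)) for r in df.itertuples()]


def read_count_table(path: str) -> dict[str, int]:
    """Read a candidate TSV into a circ_id -> BSJ count map."""
    df = pd.read_csv(path, sep="\t")
    if "circ_id" in df.columns:
        ids = df["circ_id"].astype(str)
    else:
        ids = df["chrom"].astype(str) + ":" + df["start"].astype(str) + "|" + df["end"].astype(str)
    counts = df["bsj_count"] if "bsj_count" in df.columns else df.iloc[:, 3]
    return dict(zip(ids, counts.astype(int)))


def evaluate_detection(candidates, truth_records, boundary_tol: int = 0) -> EvalResult:
    """Score in-memory detector output against simulator truth."""
    preds = [(c.junction.chrom, c.junction.acceptor, c.junction.donor) for c in candidates]
    true = [(t.junction.chrom, t.junction.acceptor, t.junction.donor) for t in truth_records]
    return match_predictions(preds, true, boundary_tol)
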