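"""Benchmarking a callset against a truth set.

Matching follows the conventional SV-benchmarking protocol: insertions and
deletions are compared separately; a call matches a truth record when the
breakpoints are within ``match_distance`` (default 500 bp) on the same
chromosome and, optionally (default on), the two lengths agree within a
size-similarity ratio (default 0.7).  Matching is greedy by ascending
breakpoint distance, one-to-one.  Precision, recall, and F1 are reported
overall and per type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import Config, SVCall


@dataclass
class MatchResult:
    true_positives: list[tuple[SVCall, SVCall]] = field(default_factory=list)
    false_positives: list[SVCall] = field(default_factory=list)
    false_negatives: list[SVCall] = field(default_factory=list)
    precision: float = 0.0
    recall: float = 0.0
    f1: float = 0.0
    precision_defined: bool = True
    recall_defined: bool = True
    per_type: dict = field(default_factory=dict)
    per_size_class: dict = field(default_factory=dict)


SIZE_CLASSES = [(50, 100), (100, 500), (500, 1_000), (1_000, 2_500),
                (2_500, 5_000), (5_000, 10_001)]


def _size_class(svlen: int) -> str:
    for lo, hi in SIZE_CLASSES:
        if lo <= svlen < hi:
            return f"{lo}-{hi - 1}"
    return "other"


def _in_window(call: SVCall, config: Config) -> bool:
    return config.min_sv_len <= call.svlen <= config.max_sv_len


def _greedy_match(calls: list[SVCall], truth: list[SVCall], config: Config):
    pairs = []
    for ci, c in enumerate(calls):
        for ti, t in enumerate(truth):
            if c.chrom != t.chrom or c.svtype != t.svtype:
                continue
            dist = abs(c.pos - t.pos)
            if dist > config.match_distance:
                continue
            if config.size_similarity_enabled:
                ratio = min(c.svlen, t.svlen) / max(c.svlen, t.svlen)
                if ratio < config.size_similarity:
                    continue
            pairs.append((dist, ci, ti))
    pairs.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    matched = []
    for dist, ci, ti in pairs:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        matched.append((calls[ci], truth[ti]))
    return matched, used_c, used_t


def match_calls(calls: list[SVCall], truth: list[SVCall],
                config: Optional[Config] = None) -> MatchResult:
    """One-to-one greedy matching by breakpoint distance, per type."""
    config = config or Config()
    calls = [c for c in calls if _in_window(c, config)]
    truth = [t for t in truth if _in_window(t, config)]
    result = MatchResult()
    for svtype in ("DEL", "INS"):
        sub_c = [c for c in calls if c.svtype == svtype]
        sub_t = [t for t in truth if t.svtype == svtype]
        matched, used_c, used_t = _greedy_match(sub_c, sub_t, config)
        fp = [c for i, c in enumerate(sub_c) if i not in used_c]
        fn = [t for i, t in enumerate(sub_t) if i not in used_t]
        result.true_positives.extend(matched)
        result.false_positives.extend(fp)
        result.false_negatives.extend(fn)
        result.per_type[svtype] = _metrics(len(matched), len(fp), len(fn))
    tp = len(result.true_positives)
    overall = _metrics(tp, len(result.false_positives),
                       len(result.false_negatives))
    result.precision = overall["precision"]
    result.recall = overall["recall"]
    result.f1 = overall["f1"]
    result.precision_defined = tp + len(result.false_positives) > 0
    result.recall_defined = tp + len(result.false_negatives) > 0
    for _, t in result.true_positives:
        cls = _size_class(t.svlen)
        result.per_size_class.setdefault(cls, {"tp": 0, "fn": 0})["tp"] += 1
    for t in result.false_negatives:
        cls = _size_class(t.svlen)
        result.per_size_class.setdefault(cls, {"tp": 0, "fn": 0})["fn"] += 1
    return result


def _metrics(tp: int, fp: int, fn: int) -> dict:
    precision = tp / (tp + fp) if tp + fp > 0 else 1.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return {"tp": tp, "fp": fp, "fn": fn, "precision": precision,
            "recall": recall, "f1": f1}


def compute_metrics(result: MatchResult) -> list[dict]:
    """Report rows: overall and per-type precision/recall/F1.

    An empty callset has undefined precision; it is reported as 1.0 with
    ``precision_defined`` False.
    """
    rows = [{
        "scope": "overall",
        "tp": len(result.true_positives),
        "fp": len(result.false_positives),
        "fn": len(result.false_negatives),
        "precision": result.precision,
        "recall": result.recall,
        "f1": result.f1,
        "precision_defined": result.precision_defined,
    }]
    for svtype, m in result.per_type.items():
        rows.append({"scope": svtype, **m})
    return rows


def write_report(rows: list[dict], path: str) -> str:
    import json

    if path.endswith(".json"):
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=2)
    else:
        cols = ["scope", "tp", "fp", "fn", "precision", "recall", "f1"]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in rows:
                fh.write("\t".join(str(row.get(c, "")) for c in cols) + "\n")
    return path
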