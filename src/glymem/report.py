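"""Set algebra of the memory study and the structured summary report.

Shared/unique differential features between the high-glucose (HG) and
memory arms, restoration under an intervention (sulforaphane or NRF2
overexpression), accessibility direction summaries, and a deterministic
machine-readable report whose integer percentages reproduce the printed
style n (p%) with round-half-away-from-zero.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable


def int_percent(num: int, den: int) -> int | None:
    """round(100 * num / den) to an integer, half away from zero.

    Returns None (printed as NA) for an empty denominator. Exact integer
    arithmetic, so 0.5 cases never suffer float rounding.
    """
    if den == 0:
        return None
    if num < 0 or den < 0:
        raise ValueError("counts must be non-negative")
    return (200 * num + den) // (2 * den)


def set_algebra(deg_a: set[str], deg_b: set[str]) -> dict:
    """Shared and unique feature sets for two contrasts, with the shared
    percentage of each side (None if a side is empty)."""
    shared = deg_a & deg_b
    return {
        "n_a": len(deg_a),
        "n_b": len(deg_b),
        "shared": shared,
        "unique_a": deg_a - deg_b,
        "unique_b": deg_b - deg_a,
        "percent_shared_of_a": int_percent(len(shared), len(deg_a)),
        "percent_shared_of_b": int_percent(len(shared), len(deg_b)),
    }


def restoration(baseline: set[str], intervention: set[str]) -> dict:
    """Split a baseline differential set by an intervention contrast.

    A feature is *restored* when it is no longer differential versus
    control under the intervention; it *remains* when it is differential in
    both. Both contrasts must be against the same control. The same logic
    serves DEG and DAR sets.
    """
    remaining = baseline & intervention
    restored = baseline - intervention
    return {
        "n_baseline": len(baseline),
        "remaining": remaining,
        "restored": restored,
        "percent_remaining": int_percent(len(remaining), len(baseline)),
        "percent_restored": int_percent(len(restored), len(baseline)),
    }


def dar_direction_summary(result) -> dict:
    """Direction counts for a differential-accessibility result table."""
    dar = result[result["is_dar"].astype(bool)]
    n_up = int((dar["direction"] == "more_accessible").sum())
    n_down = int((dar["direction"] == "less_accessible").sum())
    return {
        "n_dar": int(len(dar)),
        "n_up": n_up,
        "n_down": n_down,
        "percent_up": int_percent(n_up, len(dar)),
    }


def _sizes(d: dict) -> dict:
    """Replace set values by their sizes (sorted lists are kept out of the
    report for compactness; tables carry the memberships)."""
    out = {}
    for k, v in d.items():
        if isinstance(v, (set, frozenset)):
            out[f"n_{k}" if not k.startswith("n_") else k] = len(v)
        else:
            out[k] = v
    return out


def build_report(
    config: dict,
    expression: dict | None = None,
    accessibility: dict | None = None,
    linkage: dict | None = None,
    motifs: dict | None = None,
    strict: bool = False,
) -> dict:
    """Assemble the structured study report.

    Each section argument is a dict already shaped by its stage (set-valued
    entries are reduced to sizes). Missing sections are marked absent; in
    strict mode a missing section raises instead. The report carries the
    run configuration and thresholds so a re-run on identical inputs is
    byte-identical; no wall-clock fields are included.
    """
    sections = {"expression": expression, "accessibility": accessibility,
                "linkage": linkage, "motifs": motifs}
    report: dict = {"config": config, "sections": {}}
    for name, payload in sections.items():
        if payload is None:
            if strict:
                raise ValueError(f"missing stage output: {name}")
            report["sections"][name] = {"status": "absent"}
        else:
            report["sections"][name] = {"status": "present",
                                        **_walk_sizes(payload)}
    validate_report(report)
    return report


def _walk_sizes(obj):
    if isinstance(obj, dict):
        return {k: _walk_sizes(v) for k, v in _sizes(obj).items()}
    return obj


def validate_report(report: dict) -> None:
    """Re-derive every percentage from its own numerator/denominator and
    check partition identities; raises on any inconsistency."""
    def check(node: dict, num_key: str, den_key: str, pct_key: str) -> None:
        if num_key in node and den_key in node and pct_key in node:
            expect = int_percent(node[num_key], node[den_key])
            if node[pct_key] != expect:
                raise ValueError(f"percentage {pct_key}={node[pct_key]} "
                                 f"!= round(100*{num_key}/{den_key})={expect}")

    def walk(node) -> None:
        if not isinstance(node, dict):
            return
        check(node, "n_shared", "n_a", "percent_shared_of_a")
        check(node, "n_shared", "n_b", "percent_shared_of_b")
        check(node, "n_remaining", "n_baseline", "percent_remaining")
        check(node, "n_restored", "n_baseline", "percent_restored")
        check(node, "n_up", "n_dar", "percent_up")
        check(node, "n_concordant", "n_daes_with_target", "percent_concordant")
        if {"n_remaining", "n_restored", "n_baseline"} <= node.keys():
            if node["n_remaining"] + node["n_restored"] != node["n_baseline"]:
                raise ValueError("restored + remaining != baseline")
        if {"n_shared", "n_unique_a", "n_a"} <= node.keys():
            if node["n_shared"] + node["n_unique_a"] != node["n_a"]:
                raise ValueError("shared + unique_a != total_a")
        if {"n_dar", "n_up", "n_down"} <= node.keys():
            if node["n_up"] + node["n_down"] != node["n_dar"]:
                raise ValueError("up + down != n_dar")
        for v in node.values():
            walk(v)

    walk(report)


def report_json(report: dict) -> str:
    """Canonical serialization (sorted keys, fixed separators)."""
    return json.dumps(report, indent=2, sort_keys=True, default=_jsonable) + "\n"


def _jsonable(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def report_hash(report: dict) -> str:
    return hashlib.sha256(report_json(report).encode()).hexdigest()


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(report_json(report))


def summary_lines(report: dict) -> Iterable[str]:
    """Human-readable one-liners, printed-percentage style."""

    def render(node: dict, indent: str) -> Iterable[str]:
        flat = {k: v for k, v in node.items()
                if not isinstance(v, dict) and k != "status"}
        if flat:
            yield indent + ", ".join(f"{k}={v}" for k, v in flat.items())
        for key, val in node.items():
            if isinstance(val, dict):
                yield f"{indent}{key}:"
                yield from render(val, indent + "  ")

    yield "glymem memory report"
    for name, section in report["sections"].items():
        if section.get("status") != "present":
            yield f"  [{name}] absent"
            continue
        yield f"  [{name}]"
        yield from render(section, "    ")
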