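"""Pattern-table and report readers/writers.

Pattern TSV dialect: tab-separated, ``#`` comments, mandatory header row
``sample_id`` followed by one column per marker.  Cell tokens: ``+``/``1``/
``POS`` for present, ``-``/``0``/``NEG`` for absent (a Unicode minus is
accepted too), and an empty cell / ``NA`` / ``.`` for untested.  Untested
markers are an error in isolate mode and legal in deconvolve mode.  All
writers are byte-stable given fixed inputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

from .classify import ClassificationResult, DeconvolutionResult
from .markers import MarkerPattern

_PRESENT = {"+", "1", "POS", "TRUE", "YES"}
_ABSENT = {"-", "−", "0", "NEG", "FALSE", "NO"}
_UNTESTED = {"", "NA", ".", "?"}


class PatternTableError(ValueError):
    """Malformed pattern table; the message names the file and line."""


def read_pattern_table(
    path: str | Path, marker_ids: Sequence[str]
) -> list[MarkerPattern]:
    """Read sample marker patterns from a TSV file.

    Unknown marker columns are an error (the message lists the panel's
    marker ids); CRLF and LF files parse identically.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = [
        (i + 1, ln) for i, ln in enumerate(text.splitlines())
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise PatternTableError(f"{path}: no header row found")
    _, header_line = lines[0]
    header = [h.strip() for h in header_line.split("\t")]
    if header[0] != "sample_id":
        raise PatternTableError(
            f"{path}: first header column must be 'sample_id', got {header[0]!r}"
        )
    unknown = [h for h in header[1:] if h not in marker_ids]
    if unknown:
        raise PatternTableError(
            f"{path}: unknown marker column(s) {unknown}; panel markers are "
            f"{list(marker_ids)}"
        )

    patterns = []
    for lineno, ln in lines[1:]:
        fields = [f.strip() for f in ln.split("\t")]
        if len(fields) != len(header):
            raise PatternTableError(
                f"{path}, line {lineno}: expected {len(header)} columns, "
                f"got {len(fields)}"
            )
        present, absent = set(), set()
        for marker, tok in zip(header[1:], fields[1:]):
            t = tok.upper()
            if t in _PRESENT:
                present.add(marker)
            elif t in _ABSENT:
                absent.add(marker)
            elif t in _UNTESTED:
                continue
            else:
                raise PatternTableError(
                    f"{path}, line {lineno}: unrecognized state {tok!r} for "
                    f"{marker} (use +/-/1/0/POS/NEG or blank)"
                )
        patterns.append(
            MarkerPattern(fields[0], frozenset(present), frozenset(absent))
        )
    return patterns


def write_pattern_table(
    patterns: Iterable[MarkerPattern], marker_ids: Sequence[str], path: str | Path
) -> None:
    lines = ["sample_id\t" + "\t".join(marker_ids)]
    for p in patterns:
        cells = []
        for m in marker_ids:
            cells.append("+" if m in p.present else "-" if m in p.absent else "")
        lines.append(p.sample_id + "\t" + "\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_classification_reports(
    results: Sequence[ClassificationResult], outdir: str | Path
) -> tuple[Path, Path]:
    """Write classification results as TSV + JSON; returns the two paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tsv = outdir / "classification.tsv"
    js = outdir / "classification.json"

    lines = ["sample_id\tassigned_group\tn_positive\tsupporting_markers\tconflicts"]
    payload = []
    for r in results:
        conflicts = "; ".join(f"{g}:{reason}" for g, _m, reason in r.conflicts)
        lines.append(
            "\t".join(
                (
                    r.sample_id,
                    r.assigned_group or "NONE",
                    str(r.n_positive),
                    ",".join(sorted(r.supporting_markers)),
                    conflicts,
                )
            )
        )
        payload.append(
            {
                "sample_id": r.sample_id,
                "assigned_group": r.assigned_group,
                "n_positive": r.n_positive,
                "supporting_markers": sorted(r.supporting_markers),
                "conflicts": [
                    {"group": g, "marker": m, "reason": reason}
                    for g, m, reason in r.conflicts
                ],
            }
        )
    tsv.write_text("\n".join(lines) + "\n", encoding="utf-8")
    js.write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")
    return tsv, js


def write_deconvolution_report(
    results: Sequence[DeconvolutionResult], outdir: str | Path
) -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tsv = outdir / "deconvolution.tsv"
    js = outdir / "deconvolution.json"

    lines = ["sample_id\tcompatible_groups\texcluded_groups\tunexplained_positives"]
    payload = []
    for r in results:
        lines.append(
            "\t".join(
                (
                    r.sample_id,
                    ",".join(sorted(r.compatible_groups)),
                    ",".join(f"{g}(missing {m})" for g, m in r.excluded_groups),
                    ",".join(sorted(r.unexplained_positives)),
                )
            )
        )
        payload.append(
            {
                "sample_id": r.sample_id,
                "compatible_groups": sorted(r.compatible_groups),
                "excluded_groups": [
                    {"group": g, "missing_required": m} for g, m in r.excluded_groups
                ],
                "unexplained_positives": sorted(r.unexplained_positives),
            }
        )
    tsv.write_text("\n".join(lines) + "\n", encoding="utf-8")
    js.write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")
    return tsv, js
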