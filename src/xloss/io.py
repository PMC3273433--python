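"""TSV readers/writers and report assembly.

Canonical on-disk format is UTF-8 TSV with a header row; lines starting with
``#`` are skipped.  Schemas::

    cross:     label  mothers  total_progeny  n_x0_sons  n_xxy_daughters
    fecundity: label  mothers  eggs  pupae
    cytology:  label  endpoint  stage_range  n_positive  n_total  ovaries

JSON reports mirror the TSV contents exactly; floats are serialized with 10
significant digits.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Callable, Iterator, Sequence

from . import __version__
from .errors import ConfigurationError, SchemaError, ValidationError
from .stats import (
    CrossCounts,
    CytologyCounts,
    ExcessNulloResult,
    FecundityRecord,
    chi_square_cytology,
    chi_square_excess,
    class_frequency_percent,
    excess_nullo,
    fertility_percent,
    significance_tier,
)

__all__ = [
    "AnalysisReport",
    "read_cross_table",
    "read_fecundity_table",
    "read_cytology_table",
    "write_cross_table",
    "write_fecundity_table",
    "write_cytology_table",
    "fixture_path",
    "analyze_crosses",
    "analyze_cytology",
]

logger = logging.getLogger("xloss")

CROSS_COLUMNS = ("label", "mothers", "total_progeny", "n_x0_sons", "n_xxy_daughters")
FECUNDITY_COLUMNS = ("label", "mothers", "eggs", "pupae")
CYTOLOGY_COLUMNS = ("label", "endpoint", "stage_range", "n_positive", "n_total", "ovaries")


def fixture_path(name: str) -> Path:
    """Path of a packaged fixture TSV (raw counts of the published tables)."""
    path = resources.files("xloss").joinpath("data", name)
    return Path(str(path))


def _parse_int(value: str, column: str, lineno: int) -> int:
    try:
        as_float = float(value)
    except ValueError as exc:
        raise ValidationError(
            f"line {lineno}: column {column!r} is not a number: {value!r}"
        ) from exc
    if not as_float.is_integer():
        raise ValidationError(
            f"line {lineno}: column {column!r} must be an integer count, got {value!r}"
        )
    n = int(as_float)
    if n < 0:
        raise ValidationError(
            f"line {lineno}: column {column!r} must be non-negative, got {n}"
        )
    return n


def _iter_rows(
    path: Path | str, columns: Sequence[str]
) -> Iterator[tuple[int, dict[str, str]]]:
    path = Path(path)
    with path.open(encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header: list[str] | None = None
        n_rows = 0
        for lineno, row in enumerate(reader, start=1):
            if not row or (row[0].startswith("#")):
                continue
            if header is None:
                header = [c.strip() for c in row]
                missing = [c for c in columns if c not in header]
                if missing:
                    raise SchemaError(
                        f"{path}: missing required column(s) {', '.join(missing)}"
                    )
                continue
            if len(row) < len(header):
                raise ValidationError(
                    f"{path} line {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            n_rows += 1
            yield lineno, dict(zip(header, (c.strip() for c in row)))
        if header is None:
            raise SchemaError(f"{path}: empty file, no header row")
        if n_rows == 0:
            warnings.warn(f"{path}: no data rows", UserWarning, stacklevel=3)
            logger.warning("%s contains a header but no data rows", path)


def read_cross_table(path: Path | str) -> list[CrossCounts]:
    """Read a progeny-count table; ``n_other`` is derived from the totals."""
    out = []
    for lineno, row in _iter_rows(path, CROSS_COLUMNS):
        try:
            out.append(
                CrossCounts(
                    label=row["label"],
                    mothers=_parse_int(row["mothers"], "mothers", lineno),
                    total_progeny=_parse_int(row["total_progeny"], "total_progeny", lineno),
                    n_x0=_parse_int(row["n_x0_sons"], "n_x0_sons", lineno),
                    n_xxy=_parse_int(row["n_xxy_daughters"], "n_xxy_daughters", lineno),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} line {lineno}: {exc}") from exc
    return out


def read_fecundity_table(path: Path | str) -> list[FecundityRecord]:
    out = []
    for lineno, row in _iter_rows(path, FECUNDITY_COLUMNS):
        try:
            out.append(
                FecundityRecord(
                    label=row["label"],
                    mothers=_parse_int(row["mothers"], "mothers", lineno),
                    eggs=_parse_int(row["eggs"], "eggs", lineno),
                    pupae=_parse_int(row["pupae"], "pupae", lineno),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} line {lineno}: {exc}") from exc
    return out


def read_cytology_table(path: Path | str) -> list[CytologyCounts]:
    out = []
    for lineno, row in _iter_rows(path, CYTOLOGY_COLUMNS):
        try:
            out.append(
                CytologyCounts(
                    label=row["label"],
                    endpoint=row["endpoint"],
                    stage_range=row["stage_range"],
                    n_positive=_parse_int(row["n_positive"], "n_positive", lineno),
                    n_total=_parse_int(row["n_total"], "n_total", lineno),
                    ovaries=_parse_int(row["ovaries"], "ovaries", lineno),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} line {lineno}: {exc}") from exc
    return out


def _write_tsv(path: Path | str, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def write_cross_table(path: Path | str, rows: Sequence[CrossCounts]) -> None:
    _write_tsv(
        path,
        CROSS_COLUMNS,
        [(r.label, r.mothers, r.total_progeny, r.n_x0, r.n_xxy) for r in rows],
    )


def write_fecundity_table(path: Path | str, rows: Sequence[FecundityRecord]) -> None:
    _write_tsv(path, FECUNDITY_COLUMNS, [(r.label, r.mothers, r.eggs, r.pupae) for r in rows])


def write_cytology_table(path: Path | str, rows: Sequence[CytologyCounts]) -> None:
    _write_tsv(
        path,
        CYTOLOGY_COLUMNS,
        [
            (r.label, r.endpoint, r.stage_range, r.n_positive, r.n_total, r.ovaries)
            for r in rows
        ],
    )


def _fmt(value: Any) -> Any:
    if isinstance(value, float):
        return float(f"{value:.10g}")
    return value


@dataclass
class AnalysisReport:
    """Tidy per-genotype result rows plus run metadata.

    Every derived value in a row is recomputable from the raw counts carried
    in the same row.
    """

    rows: list[dict[str, Any]]
    metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def columns(self) -> list[str]:
        cols: list[str] = []
        for row in self.rows:
            for key in row:
                if key not in cols:
                    cols.append(key)
        return cols

    def to_tsv(self, path: Path | str) -> None:
        cols = self.columns
        rows = []
        for row in self.rows:
            rows.append(["" if row.get(c) is None else _fmt(row.get(c)) for c in cols])
        with Path(path).open("w", encoding="utf-8", newline="") as handle:
            for key, value in sorted(self.metadata.items()):
                handle.write(f"# {key}: {value}\n")
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(cols)
            writer.writerows(rows)

    def to_json(self, path: Path | str) -> None:
        payload = {
            "metadata": self.metadata,
            "rows": [{k: _fmt(v) for k, v in row.items()} for row in self.rows],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")

    def write(self, path: Path | str, fmt: str = "tsv") -> None:
        if fmt == "tsv":
            self.to_tsv(path)
        elif fmt == "json":
            self.to_json(path)
        else:
            raise ConfigurationError(f"unknown report format {fmt!r}")


def _metadata(**extra: Any) -> dict[str, Any]:
    meta = {"version": __version__}
    meta.update(extra)
    digest = hashlib.sha256(
        json.dumps(meta, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    meta["config_hash"] = digest
    return meta


def _find_control(labels: list[str], control_label: str) -> int:
    try:
        return labels.index(control_label)
    except ValueError:
        raise ConfigurationError(
            f"unknown control label {control_label!r}; available: {', '.join(labels)}"
        ) from None


def analyze_crosses(
    crosses: Sequence[CrossCounts],
    control_label: str,
    fit_fn: Callable[[CrossCounts], Any] | None = None,
    **meta: Any,
) -> AnalysisReport:
    """Table-3-shaped report: class frequencies, excess statistic, chi test.

    The control row carries no test fields.  ``fit_fn`` (e.g.
    ``inference.fit_mle``) optionally adds rate estimates per row.
    """
    control = crosses[_find_control([c.label for c in crosses], control_label)]
    rows = []
    for counts in crosses:
        result: ExcessNulloResult = excess_nullo(counts)
        row: dict[str, Any] = {
            "label": counts.label,
            "mothers": counts.mothers,
            "total_progeny": counts.total_progeny,
            "n_x0_sons": counts.n_x0,
            "n_xxy_daughters": counts.n_xxy,
            "pct_nullo": class_frequency_percent(counts.n_x0, counts.total_progeny),
            "pct_diplo": class_frequency_percent(counts.n_xxy, counts.total_progeny),
            "excess_count": result.excess_count,
            "excess_percent": result.excess_percent,
        }
        if counts.label != control_label:
            chi2, p = chi_square_excess(counts, control)
            row.update(chi2=chi2, p_value=p, tier=significance_tier(p))
            logger.info("%s vs %s: chi2=%.4g p=%.3g", counts.label, control_label, chi2, p)
        if fit_fn is not None:
            fit = fit_fn(counts)
            row.update(d_hat=fit.d_hat, l_hat=fit.l_hat, loglik=fit.loglik)
            if fit.ci_d is not None:
                row.update(d_lo=fit.ci_d[0], d_hi=fit.ci_d[1])
            if fit.ci_l is not None:
                row.update(l_lo=fit.ci_l[0], l_hi=fit.ci_l[1])
            if any(fit.at_boundary):
                logger.warning("%s: fit at parameter boundary", counts.label)
        rows.append(row)
    return AnalysisReport(rows=rows, metadata=_metadata(control=control_label, **meta))


def analyze_cytology(
    records: Sequence[CytologyCounts], control_label: str, **meta: Any
) -> AnalysisReport:
    """Figure-2-shaped report: positive fractions and chi tests vs. a control.

    Tests are computed within endpoint (a label may appear once per endpoint).
    """
    controls = {r.endpoint: r for r in records if r.label == control_label}
    if not controls:
        _find_control([r.label for r in records], control_label)  # raises
    rows = []
    for rec in records:
        row: dict[str, Any] = {
            "label": rec.label,
            "endpoint": rec.endpoint,
            "stage_range": rec.stage_range,
            "n_positive": rec.n_positive,
            "n_total": rec.n_total,
            "ovaries": rec.ovaries,
            "pct_positive": class_frequency_percent(rec.n_positive, rec.n_total),
        }
        control = controls.get(rec.endpoint)
        if rec.label != control_label and control is not None:
            chi2, p = chi_square_cytology(rec, control)
            row.update(chi2=chi2, p_value=p, tier=significance_tier(p))
        rows.append(row)
    return AnalysisReport(rows=rows, metadata=_metadata(control=control_label, **meta))
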