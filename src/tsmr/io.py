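"""Reading, validating and writing GWAS summary-statistic tables.

The canonical on-disk format is delimited text (tab by default, comma
accepted) with header columns ``SNP CHR BP EA OA EAF BETA SE P N``.
Source GWASs use many column dialects; a ``column_map`` renames source
headers onto the canonical ones without any unit conversion.

Validation is total: a malformed row never raises, it is collected in a
:class:`RowIssue` list so callers can audit what was excluded.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SummaryStatRecord",
    "RowIssue",
    "LDMatrix",
    "read_summary_stats",
    "write_summary_stats",
    "read_ld_matrix",
    "write_ld_matrix",
]

VALID_BASES = frozenset("ACGT")

#: canonical header name -> record field name
CANONICAL_COLUMNS = {
    "SNP": "snp_id",
    "CHR": "chrom",
    "BP": "pos",
    "EA": "effect_allele",
    "OA": "other_allele",
    "EAF": "eaf",
    "BETA": "beta",
    "SE": "se",
    "P": "pval",
    "N": "n",
}

MANDATORY = ("SNP", "EA", "OA", "BETA", "SE", "P")

_MISSING = {"", "NA", "NAN", "NONE", "."}


@dataclass(slots=True)
class SummaryStatRecord:
    """One variant's association summary in one GWAS.

    ``beta`` is the per-SD (or log-odds) effect of the effect allele,
    ``eaf`` its frequency; ``eaf`` and ``n`` may be missing (``None``).
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: float | None = None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if self.effect_allele not in VALID_BASES or self.other_allele not in VALID_BASES:
            problems.append("allele not a single A/C/G/T base (indel or multi-allelic)")
        elif self.effect_allele == self.other_allele:
            problems.append("identical effect and other alleles")
        if not np.isfinite(self.beta):
            problems.append("non-finite beta")
        if not (np.isfinite(self.se) and self.se > 0):
            problems.append("non-positive standard error")
        if not (np.isfinite(self.pval) and 0 < self.pval <= 1):
            problems.append("p-value outside (0, 1]")
        if self.eaf is not None and not (0 < self.eaf < 1):
            problems.append("eaf outside (0, 1)")
        if self.pos < 1:
            problems.append("position < 1")
        return problems


@dataclass(slots=True)
class RowIssue:
    """A rejected input row: its 1-based line number and why."""

    line: int
    snp_id: str
    message: str


@dataclass
class LDMatrix:
    """Pairwise squared-correlation (r²) matrix over named variants."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValueError(f"r2 shape {self.r2.shape} does not match {k} snp_ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12, rtol=0):
            raise ValueError("r2 matrix is not symmetric")
        if not np.all(np.diag(self.r2) == 1.0):
            raise ValueError("r2 diagonal must be exactly 1")
        if np.any((self.r2 < 0) | (self.r2 > 1)):
            raise ValueError("r2 entries must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}
        if len(self._index) != k:
            raise ValueError("duplicate snp_ids in LD matrix")

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def value(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def subset(self, snp_ids: Sequence[str]) -> "LDMatrix":
        idx = [self._index[s] for s in snp_ids]
        return LDMatrix(list(snp_ids), self.r2[np.ix_(idx, idx)])


def _detect_sep(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _to_float(token: str) -> float | None:
    token = token.strip()
    if token.upper() in _MISSING:
        return None
    return float(token)  # may raise ValueError


def read_summary_stats(
    source,
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[SummaryStatRecord], list[RowIssue]]:
    """Read a delimited summary-statistics table.

    Parameters
    ----------
    source : path-like or text stream
        Tab- or comma-delimited text with a header line; the delimiter is
        auto-detected from the header.
    column_map : mapping, optional
        Source header name -> canonical name (``SNP CHR BP EA OA EAF BETA
        SE P N``, case-insensitive). A pure renaming, no unit conversion.

    Returns
    -------
    (records, issues)
        Validated records, and one :class:`RowIssue` per rejected row
        (1-based line numbers, header = line 1). Rows are never silently
        dropped.

    Raises
    ------
    ValueError
        If a mandatory column (SNP/EA/OA/BETA/SE/P) is absent.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    lines = text.splitlines()
    if not lines:
        raise ValueError("empty input: no header line")
    sep = _detect_sep(lines[0])
    header = [h.strip() for h in lines[0].split(sep)]

    rename = {k.upper(): v.upper() for k, v in (column_map or {}).items()}
    canon = []
    for h in header:
        h_up = rename.get(h.upper(), h.upper())
        canon.append(h_up if h_up in CANONICAL_COLUMNS else None)
    col_of = {}
    for i, c in enumerate(canon):
        if c is not None and c not in col_of:
            col_of[c] = i
    for m in MANDATORY:
        if m not in col_of:
            raise ValueError(f"missing mandatory column: {m}")

    records: list[SummaryStatRecord] = []
    issues: list[RowIssue] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        toks = line.split(sep)
        if len(toks) < len(header):
            issues.append(RowIssue(lineno, "", "short row"))
            continue

        def cell(name: str) -> str:
            i = col_of.get(name)
            return toks[i].strip() if i is not None else ""

        snp = cell("SNP")
        try:
            eaf = _to_float(cell("EAF")) if "EAF" in col_of else None
            n = _to_float(cell("N")) if "N" in col_of else None
            pos_tok = cell("BP") if "BP" in col_of else ""
            pos = int(float(pos_tok)) if pos_tok.upper() not in _MISSING else 1
            beta = _to_float(cell("BETA"))
            se = _to_float(cell("SE"))
            pval = _to_float(cell("P"))
            if beta is None or se is None or pval is None:
                issues.append(RowIssue(lineno, snp, "missing beta/se/p value"))
                continue
            rec = SummaryStatRecord(
                snp_id=snp,
                chrom=cell("CHR") if "CHR" in col_of else "NA",
                pos=pos,
                effect_allele=cell("EA").upper(),
                other_allele=cell("OA").upper(),
                eaf=eaf,
                beta=beta,
                se=se,
                pval=pval,
                n=n,
            )
        except ValueError as exc:
            issues.append(RowIssue(lineno, snp, f"unparseable numeric: {exc}"))
            continue
        problems = rec.validate()
        if problems:
            issues.append(RowIssue(lineno, snp, "; ".join(problems)))
        else:
            records.append(rec)
    return records, issues


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        return format(x, ".17g")  # exact float round-trip
    return str(x)


def write_summary_stats(records: Iterable[SummaryStatRecord], dest) -> None:
    """Write records as canonical TSV; ``read(write(x)) == x`` exactly."""
    out = _io.StringIO()
    out.write("SNP\tCHR\tBP\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n")
    for r in records:
        out.write(
            "\t".join(
                [
                    r.snp_id,
                    r.chrom,
                    str(r.pos),
                    r.effect_allele,
                    r.other_allele,
                    _fmt(r.eaf),
                    _fmt(r.beta),
                    _fmt(r.se),
                    _fmt(r.pval),
                    _fmt(r.n),
                ]
            )
            + "\n"
        )
    _write_text(dest, out.getvalue())


def write_ld_matrix(ld: LDMatrix, dest) -> None:
    out = _io.StringIO()
    out.write("SNP\t" + "\t".join(ld.snp_ids) + "\n")
    for i, s in enumerate(ld.snp_ids):
        out.write(s + "\t" + "\t".join(format(v, ".17g") for v in ld.r2[i]) + "\n")
    _write_text(dest, out.getvalue())


def read_ld_matrix(source) -> LDMatrix:
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    snp_ids = lines[0].split("\t")[1:]
    rows = []
    for ln in lines[1:]:
        rows.append([float(t) for t in ln.split("\t")[1:]])
    return LDMatrix(snp_ids, np.array(rows))


def _write_text(dest, text: str) -> None:
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)
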