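"""Readers and writers for the plain-text formats the pipeline exchanges.

GEO Series Matrix text and SOFT platform annotation tables are read with
small line parsers (the formats are line-oriented TSV with sentinel lines);
everything else is headered, tab-separated UTF-8 with '.' decimals and empty
cells for missing values.  Gene symbols are compared case-insensitively after
trimming; probe identifiers are case-sensitive.
"""

from __future__ import annotations

import csv
import io as _io
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .assay_qc import DilutionSeries, ReplicateSet
from .primer_rules import EditingSite, PrimerPairRecord, SnpAnnotation
from .screening import ExpressionDataset
from .stability import CqMatrix

__all__ = [
    "ParseError",
    "parse_series_matrix",
    "write_series_matrix",
    "parse_platform_table",
    "map_probes_to_genes",
    "read_expression_tsv",
    "read_groups_tsv",
    "write_groups_tsv",
    "read_candidate_list",
    "write_candidate_list",
    "read_cq_table",
    "write_cq_table",
    "read_efficiency_tsv",
    "read_dilution_tsv",
    "write_dilution_tsv",
    "read_replicates_tsv",
    "write_replicates_tsv",
    "read_primer_table",
    "write_primer_table",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line/cell."""


_TABLE_BEGIN = "!series_matrix_table_begin"
_TABLE_END = "!series_matrix_table_end"


def _unquote(tok: str) -> str:
    tok = tok.strip()
    if len(tok) >= 2 and tok[0] == tok[-1] == '"':
        tok = tok[1:-1]
    return tok


def _to_float(tok: str, line_no: int, col: str, probe: str) -> float:
    tok = _unquote(tok)
    if tok == "" or tok.lower() in {"null", "na", "nan"}:
        return np.nan
    try:
        return float(tok)
    except ValueError:
        raise ParseError(
            f"line {line_no}: non-numeric cell {tok!r} (probe {probe}, sample {col})"
        ) from None


def parse_series_matrix(path) -> ExpressionDataset:
    """Read a GEO Series Matrix text file into an :class:`ExpressionDataset`.

    Sample identifiers come from the table header row; metadata lines
    (``!Key<TAB>value...``) are retained verbatim for group-assignment hints.
    Groups are left unassigned — supply them from a two-column sample/group
    table.  Cells that are empty or "null" become missing.
    """
    path = Path(path)
    metadata: dict[str, list[str]] = {}
    header: list[str] | None = None
    rows: list[tuple[str, list[float]]] = []
    in_table = False
    saw_begin = saw_end = False
    with path.open(encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(_TABLE_BEGIN):
                in_table, saw_begin = True, True
                continue
            if line.startswith(_TABLE_END):
                in_table = False
                saw_end = True
                continue
            if not in_table:
                if line.startswith("!"):
                    key, *vals = line.split("\t")
                    metadata.setdefault(key.lstrip("!"), []).extend(
                        _unquote(v) for v in vals
                    )
                continue
            toks = line.split("\t")
            if header is None:
                header = [_unquote(t) for t in toks[1:]]
                continue
            probe = _unquote(toks[0])
            vals = [
                _to_float(t, line_no, header[i] if i < len(header) else f"col{i}", probe)
                for i, t in enumerate(toks[1:])
            ]
            if len(vals) != len(header):
                raise ParseError(
                    f"line {line_no}: expected {len(header)} values, got {len(vals)}"
                )
            rows.append((probe, vals))
    if not saw_begin or not saw_end:
        missing = _TABLE_BEGIN if not saw_begin else _TABLE_END
        raise ParseError(f"{path.name}: missing {missing} line")
    if header is None:
        raise ParseError(f"{path.name}: series matrix table has no header row")
    values = pd.DataFrame(
        [v for _, v in rows], index=[p for p, _ in rows], columns=header, dtype=float
    )
    return ExpressionDataset(
        dataset_id=path.stem, values=values, metadata=metadata
    )


def write_series_matrix(dataset: ExpressionDataset, path) -> None:
    """Write a minimal Series Matrix file (round-trips with the parser)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f'!Series_geo_accession\t"{dataset.dataset_id}"\n')
        for key, vals in dataset.metadata.items():
            if key == "Series_geo_accession":
                continue
            fh.write("!" + key + "\t" + "\t".join(f'"{v}"' for v in vals) + "\n")
        fh.write(_TABLE_BEGIN + "\n")
        fh.write('"ID_REF"\t' + "\t".join(f'"{s}"' for s in dataset.values.columns) + "\n")
        for probe, row in dataset.values.iterrows():
            cells = ["null" if not np.isfinite(v) else repr(float(v)) for v in row]
            fh.write(f'"{probe}"\t' + "\t".join(cells) + "\n")
        fh.write(_TABLE_END + "\n")


def parse_platform_table(path) -> pd.DataFrame:
    """Read the table section of a GEO SOFT platform annotation file.

    Accepts either a bare headered TSV or a SOFT file whose table sits
    between ``!platform_table_begin`` and ``!platform_table_end``; leading
    ``#``/``!``/``^`` metadata lines are skipped.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if any(l.startswith("!platform_table_begin") for l in lines):
        start = next(i for i, l in enumerate(lines) if l.startswith("!platform_table_begin")) + 1
        end = next(
            (i for i, l in enumerate(lines) if l.startswith("!platform_table_end")),
            len(lines),
        )
        body = lines[start:end]
    else:
        body = [l for l in lines if l and not l.startswith(("#", "!", "^"))]
    if not body:
        raise ParseError(f"{path.name}: no platform table found")
    return pd.read_csv(_io.StringIO("\n".join(body)), sep="\t", dtype=str)


_SYMBOL_SPLIT = re.compile(r"\s*(?:///|;)\s*")


def map_probes_to_genes(
    platform: pd.DataFrame, symbol_column: str, probe_column: str | None = None
) -> dict[str, tuple[str, ...]]:
    """Probe -> gene-symbol mapping from a platform annotation table.

    Multi-symbol cells are split on ``///`` or ``;``; symbols are upper-cased;
    probes without a symbol are omitted.
    """
    if probe_column is None:
        probe_column = platform.columns[0]
    for col in (probe_column, symbol_column):
        if col not in platform.columns:
            raise ParseError(f"platform table lacks column {col!r}")
    mapping: dict[str, tuple[str, ...]] = {}
    for probe, cell in zip(platform[probe_column], platform[symbol_column]):
        if pd.isna(cell) or not str(cell).strip():
            continue
        syms = tuple(
            s.upper() for s in _SYMBOL_SPLIT.split(str(cell).strip()) if s
        )
        if syms:
            mapping[str(probe)] = syms
    return mapping


# ---------------------------------------------------------------------------
# generic TSV tables
# ---------------------------------------------------------------------------

def read_expression_tsv(path, dataset_id: str | None = None) -> ExpressionDataset:
    """Probes in rows, samples in columns, header row of sample ids."""
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionDataset(
        dataset_id=dataset_id or path.stem, values=values.astype(float)
    )


def read_groups_tsv(path) -> dict[str, str]:
    """Two-column (sample, group) table, with or without a header."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError("groups table needs two columns: sample, group")
    first = df.columns[:2]
    if not {first[0].lower(), first[1].lower()} & {"sample", "group"}:
        # headerless file: first row is data
        df = pd.read_csv(path, sep="\t", dtype=str, header=None)
    return dict(zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip()))


def write_groups_tsv(groups: dict[str, str], path) -> None:
    pd.DataFrame(
        {"sample": list(groups), "group": list(groups.values())}
    ).to_csv(path, sep="\t", index=False)


def read_candidate_list(path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments skipped."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        sym = line.strip()
        if sym and not sym.startswith("#"):
            out.append(sym.upper())
    return out


def write_candidate_list(genes: list[str], path) -> None:
    Path(path).write_text("\n".join(genes) + "\n", encoding="utf-8")


def read_cq_table(path, groups_path=None, efficiency_path=None) -> CqMatrix:
    """Cq table: first column sample id, remaining columns gene symbols."""
    cq = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    cq.columns = [c.strip().upper() for c in cq.columns]
    groups = read_groups_tsv(groups_path) if groups_path else None
    efficiency = read_efficiency_tsv(efficiency_path) if efficiency_path else {}
    return CqMatrix(cq=cq, groups=groups, efficiency=efficiency)


def write_cq_table(cq: CqMatrix, path) -> None:
    cq.cq.rename_axis("sample").to_csv(path, sep="\t")


def read_efficiency_tsv(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError("efficiency table needs columns: gene, E")
    return {
        str(g).strip().upper(): float(e)
        for g, e in zip(df.iloc[:, 0], df.iloc[:, 1])
    }


def read_dilution_tsv(path) -> dict[str, DilutionSeries]:
    """Long-format dilution table: gene, log10_dilution, replicate, cq."""
    df = pd.read_csv(path, sep="\t")
    needed = {"gene", "log10_dilution", "cq"}
    if not needed <= set(df.columns):
        raise ParseError(f"dilution table needs columns {sorted(needed)}")
    out: dict[str, DilutionSeries] = {}
    for gene, sub in df.groupby("gene", sort=False):
        points: dict[float, list[float]] = {}
        for lv, grp in sub.groupby("log10_dilution", sort=False):
            points[float(lv)] = [
                float(c) if pd.notna(c) else np.nan for c in grp["cq"]
            ]
        out[str(gene).upper()] = DilutionSeries(gene=str(gene).upper(), points=points)
    return out


def write_dilution_tsv(series: dict[str, DilutionSeries], path) -> None:
    rows = []
    for gene, ds in series.items():
        for lv in ds.levels():
            for rep, cq in enumerate(ds.points[lv], start=1):
                rows.append(
                    {
                        "gene": gene,
                        "log10_dilution": lv,
                        "replicate": rep,
                        "cq": "" if not np.isfinite(cq) else cq,
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_replicates_tsv(path) -> list[ReplicateSet]:
    """Replicates table: gene, run_id, replicate, cq."""
    df = pd.read_csv(path, sep="\t")
    needed = {"gene", "run_id", "cq"}
    if not needed <= set(df.columns):
        raise ParseError(f"replicates table needs columns {sorted(needed)}")
    out = []
    for (gene, run), sub in df.groupby(["gene", "run_id"], sort=False):
        out.append(
            ReplicateSet(
                gene=str(gene).upper(),
                run_id=str(run),
                cq_values=[float(c) for c in sub["cq"] if pd.notna(c)],
            )
        )
    return out


def write_replicates_tsv(sets: list[ReplicateSet], path) -> None:
    rows = [
        {"gene": s.gene, "run_id": s.run_id, "replicate": i + 1, "cq": c}
        for s in sets
        for i, c in enumerate(s.cq_values)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# primer tables
# ---------------------------------------------------------------------------

def _fmt_triplets(items) -> str:
    return ";".join(items)


def _parse_freq(tok: str) -> float | None:
    tok = tok.strip()
    if tok == "" or tok.upper() in {"NA", "UNKNOWN", "?"}:
        return None
    return float(tok)


def read_primer_table(path) -> list[PrimerPairRecord]:
    """One row per candidate pair; SNP/editing cells are ``primer:pos[:freq]``
    triplets separated by ';' (empty cell = none)."""
    records = []
    with Path(path).open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row_no, row in enumerate(reader, start=2):
            try:
                snps = []
                for trip in (row.get("snps") or "").split(";"):
                    trip = trip.strip()
                    if not trip:
                        continue
                    primer, pos, *freq = trip.split(":")
                    snps.append(
                        SnpAnnotation(
                            primer.strip().upper(),
                            int(pos),
                            _parse_freq(freq[0]) if freq else None,
                        )
                    )
                sites = []
                for trip in (row.get("editing_sites") or "").split(";"):
                    trip = trip.strip()
                    if not trip:
                        continue
                    primer, pos = trip.split(":")[:2]
                    sites.append(EditingSite(primer.strip().upper(), int(pos)))
                records.append(
                    PrimerPairRecord(
                        gene=row["gene"].strip().upper(),
                        forward=row["forward"],
                        reverse=row["reverse"],
                        amplicon_bp=int(row["amplicon_bp"]),
                        spans_exon_junction=row.get("spans_exon_junction", "true")
                        .strip()
                        .lower()
                        in {"1", "true", "yes"},
                        snps=snps,
                        editing_sites=sites,
                        hairpin_tm={
                            "F": float(row["hairpin_tm_f"]),
                            "R": float(row["hairpin_tm_r"]),
                        },
                        homodimer_dg={
                            "F": float(row["homodimer_dg_f"]),
                            "R": float(row["homodimer_dg_r"]),
                        },
                        heterodimer_dg=float(row["heterodimer_dg"]),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ParseError(f"primer table row {row_no}: {exc}") from exc
    return records


def write_primer_table(records: list[PrimerPairRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "gene": r.gene,
                "forward": r.forward,
                "reverse": r.reverse,
                "amplicon_bp": r.amplicon_bp,
                "spans_exon_junction": str(r.spans_exon_junction).lower(),
                "snps": _fmt_triplets(
                    f"{s.primer}:{s.pos_from_3prime}:"
                    f"{'' if s.allele_frequency is None else repr(s.allele_frequency)}"
                    for s in r.snps
                ),
                "editing_sites": _fmt_triplets(
                    f"{e.primer}:{e.pos_from_3prime}" for e in r.editing_sites
                ),
                "hairpin_tm_f": r.hairpin_tm.get("F", ""),
                "hairpin_tm_r": r.hairpin_tm.get("R", ""),
                "homodimer_dg_f": r.homodimer_dg.get("F", ""),
                "homodimer_dg_r": r.homodimer_dg.get("R", ""),
                "heterodimer_dg": "" if r.heterodimer_dg is None else r.heterodimer_dg,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
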