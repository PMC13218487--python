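"""Partitioned binary cognate matrices: container, I/O, ascertainment filter.

Cognate-coded lexical data is binarised: each cognate set is one binary
character (absent/present per language), and characters are grouped into
partitions by the meaning (Swadesh item) they code for.  Because data are
collected per meaning, a cognate set absent in *every* language can never be
observed — the ascertainment bias this package studies.

Two on-disk dialects are supported: a long-format CSV
(``language,meaning,cognate_id,value``) and standard NEXUS (DATA block with
symbols "01" plus a SETS block whose charsets name the meanings).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

MISSING = -1  # internal code for '?'


@dataclass
class CognateMatrix:
    """Languages x cognate-sets binary matrix with a meaning partition map.

    ``values`` holds 0/1 entries (``-1`` codes missing data, representable but
    rejected by the likelihood machinery).  ``partition_map`` assigns every
    column to exactly one meaning.  ``ascertained=True`` asserts that no
    column is absent in all languages.
    """

    languages: list[str]
    columns: list[str]
    values: np.ndarray
    partition_map: dict[str, str]  # column id -> meaning id
    ascertained: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if len(set(self.languages)) != len(self.languages):
            raise ValueError("duplicate language names")
        if self.values.shape != (len(self.languages), len(self.columns)):
            raise ValueError("values shape does not match languages x columns")
        if not set(np.unique(self.values)) <= {0, 1, MISSING}:
            raise ValueError("entries must be 0, 1 or missing")
        missing_cols = [c for c in self.columns if c not in self.partition_map]
        if missing_cols:
            raise ValueError(f"columns without meaning assignment: {missing_cols[:5]}")
        if not self.columns:
            raise ValueError("matrix has no cognate columns")
        if self.ascertained and not self._no_all_absent():
            raise ValueError("ascertained matrix contains an all-absent column")

    def _no_all_absent(self) -> bool:
        return bool(np.all((self.values == 1).any(axis=0)))

    @property
    def meanings(self) -> list[str]:
        """Meanings in first-appearance column order."""
        seen: dict[str, None] = {}
        for c in self.columns:
            seen.setdefault(self.partition_map[c], None)
        return list(seen)

    def meaning_sizes(self) -> dict[str, int]:
        """Observed cognate-set count k_i per meaning."""
        sizes: dict[str, int] = {m: 0 for m in self.meanings}
        for c in self.columns:
            sizes[self.partition_map[c]] += 1
        return sizes

    def column_indices(self, meaning: str) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.columns) if self.partition_map[c] == meaning],
            dtype=int,
        )

    def has_missing(self) -> bool:
        return bool(np.any(self.values == MISSING))


def apply_ascertainment_filter(m: CognateMatrix) -> tuple[CognateMatrix, dict[str, int]]:
    """Drop all-absent columns, returning the filtered matrix and per-meaning
    removal counts.

    Raises if some meaning loses every column (a degenerate simulation the
    caller must decide how to handle).
    """
    keep = (m.values == 1).any(axis=0)
    removed: dict[str, int] = {mn: 0 for mn in m.meanings}
    for i, c in enumerate(m.columns):
        if not keep[i]:
            removed[m.partition_map[c]] += 1
    cols = [c for i, c in enumerate(m.columns) if keep[i]]
    surviving_meanings = {m.partition_map[c] for c in cols}
    dead = [mn for mn in m.meanings if mn not in surviving_meanings]
    if dead:
        raise ValueError(f"meanings left with zero observable columns: {dead}")
    out = CognateMatrix(
        languages=list(m.languages),
        columns=cols,
        values=m.values[:, keep],
        partition_map={c: m.partition_map[c] for c in cols},
        ascertained=True,
    )
    return out, removed


@dataclass
class PartitionSpec:
    """How columns are grouped into rate partitions and weighted.

    ``scheme``: ``per_meaning`` (one partition per meaning), ``binned``
    (meanings binned by their observed cognate-set count, bins 1-5, 6-10, ...)
    or ``single``.  ``weights_mode``: ``cognates`` (observed column counts),
    ``meanings`` (meaning counts per partition) or ``equal``.
    """

    scheme: str = "per_meaning"
    bin_width: int = 5
    weights_mode: str = "equal"

    def __post_init__(self) -> None:
        if self.scheme not in ("per_meaning", "binned", "single"):
            raise ValueError(f"unknown partition scheme {self.scheme!r}")
        if self.weights_mode not in ("cognates", "meanings", "equal"):
            raise ValueError(f"unknown weights mode {self.weights_mode!r}")
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")


@dataclass
class Partition:
    name: str
    column_idx: np.ndarray
    n_meanings: int
    weight: float = 1.0


def build_partitions(m: CognateMatrix, spec: PartitionSpec) -> list[Partition]:
    """Group columns into partitions with weights per ``spec``.

    Binned partitions are ordered by bin lower edge; meanings tie-break by
    name so outputs are deterministic.
    """
    sizes = m.meaning_sizes()
    if spec.scheme == "single":
        parts = [
            Partition(
                name="all",
                column_idx=np.arange(len(m.columns)),
                n_meanings=len(sizes),
            )
        ]
    elif spec.scheme == "per_meaning":
        parts = [
            Partition(name=mn, column_idx=m.column_indices(mn), n_meanings=1)
            for mn in m.meanings
        ]
    else:  # binned
        by_bin: dict[int, list[str]] = {}
        for mn in sorted(sizes):
            b = (sizes[mn] - 1) // spec.bin_width
            by_bin.setdefault(b, []).append(mn)
        parts = []
        for b in sorted(by_bin):
            lo, hi = b * spec.bin_width + 1, (b + 1) * spec.bin_width
            idx = np.concatenate([m.column_indices(mn) for mn in by_bin[b]])
            parts.append(
                Partition(
                    name=f"{lo}-{hi}",
                    column_idx=np.sort(idx),
                    n_meanings=len(by_bin[b]),
                )
            )
    for p in parts:
        if spec.weights_mode == "cognates":
            p.weight = float(len(p.column_idx))
        elif spec.weights_mode == "meanings":
            p.weight = float(p.n_meanings)
        else:
            p.weight = 1.0
    return parts


# ---------------------------------------------------------------------------
# I/O


def read_matrix(path: str | Path, format: str | None = None) -> CognateMatrix:
    """Read a cognate matrix from CSV or NEXUS (inferred from the suffix)."""
    path = Path(path)
    if format is None:
        format = "nexus" if path.suffix.lower() in (".nex", ".nexus") else "csv"
    if format == "csv":
        return _read_csv(path)
    if format == "nexus":
        return _read_nexus(path)
    raise ValueError(f"unknown format {format!r}")


def write_matrix(m: CognateMatrix, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "nexus" if path.suffix.lower() in (".nex", ".nexus") else "csv"
    if format == "csv":
        _write_csv(m, path)
    elif format == "nexus":
        _write_nexus(m, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_csv(path: Path) -> CognateMatrix:
    df = pd.read_csv(path, dtype=str)
    required = {"language", "meaning", "cognate_id", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"CSV must have columns {sorted(required)}")
    if df.empty:
        raise ValueError("empty cognate table")
    languages = list(dict.fromkeys(df["language"]))
    columns = list(dict.fromkeys(df["cognate_id"]))
    part: dict[str, str] = {}
    for cid, mn in zip(df["cognate_id"], df["meaning"]):
        if part.setdefault(cid, mn) != mn:
            raise ValueError(f"cognate {cid!r} assigned to multiple meanings")
    values = np.full((len(languages), len(columns)), MISSING, dtype=np.int8)
    li = {l: i for i, l in enumerate(languages)}
    ci = {c: j for j, c in enumerate(columns)}
    for lang, cid, val in zip(df["language"], df["cognate_id"], df["value"]):
        v = val.strip()
        if v == "?":
            code = MISSING
        elif v in ("0", "1"):
            code = int(v)
        else:
            raise ValueError(f"non-binary symbol {val!r} for {lang}/{cid}")
        values[li[lang], ci[cid]] = code
    return CognateMatrix(languages, columns, values, part)


def _write_csv(m: CognateMatrix, path: Path) -> None:
    rows = []
    for i, lang in enumerate(m.languages):
        for j, cid in enumerate(m.columns):
            v = m.values[i, j]
            rows.append(
                {
                    "language": lang,
                    "meaning": m.partition_map[cid],
                    "cognate_id": cid,
                    "value": "?" if v == MISSING else str(int(v)),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def _read_nexus(path: Path) -> CognateMatrix:
    cm = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    languages = [t.label for t in cm.taxon_namespace]
    nchar = max(len(cm[t]) for t in cm.taxon_namespace)
    values = np.full((len(languages), nchar), MISSING, dtype=np.int8)
    for i, taxon in enumerate(cm.taxon_namespace):
        for j, ch in enumerate(cm[taxon]):
            sym = str(ch)
            if sym == "?":
                values[i, j] = MISSING
            elif sym in ("0", "1"):
                values[i, j] = int(sym)
            else:
                raise ValueError(f"non-binary symbol {sym!r} in NEXUS matrix")
    if not cm.character_subsets:
        raise ValueError("NEXUS matrix has no charsets naming the meanings")
    part: dict[str, str] = {}
    columns = [f"c{j}" for j in range(nchar)]
    for name, subset in cm.character_subsets.items():
        for j in subset.character_indices:
            columns[j] = f"{name}_{j}"
            part[columns[j]] = name
    unassigned = [j for j in range(nchar) if columns[j] == f"c{j}"]
    if unassigned:
        raise ValueError(f"columns without meaning assignment: {unassigned[:5]}")
    return CognateMatrix(languages, columns, values, part)


def _write_nexus(m: CognateMatrix, path: Path) -> None:
    buf = io.StringIO()
    buf.write("#NEXUS\n\nBEGIN DATA;\n")
    buf.write(f"DIMENSIONS NTAX={len(m.languages)} NCHAR={len(m.columns)};\n")
    buf.write('FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;\nMATRIX\n')
    width = max(len(l) for l in m.languages) + 2
    for i, lang in enumerate(m.languages):
        row = "".join(
            "?" if v == MISSING else str(int(v)) for v in m.values[i]
        )
        safe = lang.replace(" ", "_")
        buf.write(f"{safe:<{width}}{row}\n")
    buf.write(";\nEND;\n\nBEGIN SETS;\n")
    # contiguous runs per meaning (columns are grouped by meaning on write)
    for mn in m.meanings:
        idx = m.column_indices(mn) + 1  # NEXUS is 1-based
        runs = _runs(idx)
        spec = " ".join(f"{a}-{b}" if a != b else f"{a}" for a, b in runs)
        buf.write(f"charset {mn} = {spec};\n")
    buf.write("END;\n")
    Path(path).write_text(buf.getvalue())


def _runs(idx: np.ndarray) -> list[tuple[int, int]]:
    runs: list[tuple[int, int]] = []
    start = prev = int(idx[0])
    for v in idx[1:]:
        v = int(v)
        if v == prev + 1:
            prev = v
            continue
        runs.append((start, prev))
        start = prev = v
    runs.append((start, prev))
    return runs


def all_absent_fraction(n_total: int, n_observed: int) -> float:
    """Fraction of simulated columns removed by the ascertainment filter."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 1.0 - n_observed / n_total


def table1_fixture_path() -> Path:
    """Path of the bundled worked-example matrix (five Slavic languages,
    meanings *two* and *belly*)."""
    return Path(__file__).parent / "data" / "table1_slavic.csv"
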