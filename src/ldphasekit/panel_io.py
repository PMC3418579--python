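"""Genotype panel and marker map containers plus PLINK-text I/O.

A panel stores diploid dosages of each marker's *counted* allele
(0, 1, 2, or -1 for missing).  Which allele is counted matters: the sign
of the LD phase r flips when the counted allele flips, so the orientation
of every marker is recorded in a JSON sidecar next to the .map file and
re-applied on read.  Without a consistent orientation, signed-r
comparisons across populations are meaningless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

_LEGAL_ALLELES = {"A", "C", "G", "T", "0", "1", "2"}


@dataclass
class MarkerMap:
    """Per-marker chromosome, 1-based bp position, and allele orientation.

    ``allele_other``/``allele_counted`` give the two allele labels; dosage
    counts copies of ``allele_counted``.
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    allele_other: np.ndarray
    allele_counted: np.ndarray

    def __post_init__(self) -> None:
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        self.allele_other = np.asarray(self.allele_other, dtype=object)
        self.allele_counted = np.asarray(self.allele_counted, dtype=object)
        if len(set(self.marker_id)) != self.n_markers:
            raise ValueError("duplicate marker ids")
        if np.any(self.position_bp <= 0):
            raise ValueError("positions must be strictly positive (1-based)")
        for chrom in pd.unique(self.chromosome):
            pos = self.position_bp[self.chromosome == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions on chromosome {chrom} must be strictly "
                    "increasing (sort the map explicitly; ties are rejected)"
                )

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chromosome": self.chromosome,
                "position_bp": self.position_bp,
                "allele_other": self.allele_other,
                "allele_counted": self.allele_counted,
            }
        )

    def orientation(self) -> dict[str, str]:
        """marker_id -> counted allele label."""
        return dict(zip(self.marker_id, self.allele_counted))

    def subset(self, index: np.ndarray) -> "MarkerMap":
        return MarkerMap(
            self.marker_id[index],
            self.chromosome[index],
            self.position_bp[index],
            self.allele_other[index],
            self.allele_counted[index],
        )


@dataclass
class GenotypePanel:
    """Individuals x markers dosage matrix for one population.

    dosages[i, m] counts copies of marker m's counted allele in
    individual i: 0, 1, 2, or MISSING (-1).
    """

    individual_ids: list[str]
    population_label: str
    dosages: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if len(self.individual_ids) != len(set(self.individual_ids)):
            raise ValueError("duplicate individual ids")
        if self.dosages.ndim != 2 or self.dosages.shape[0] != len(self.individual_ids):
            raise ValueError("dosage matrix shape does not match individual ids")
        legal = np.isin(self.dosages, (MISSING, 0, 1, 2))
        if not legal.all():
            raise ValueError("dosages must be in {0, 1, 2, missing}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def subset_markers(self, index: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            list(self.individual_ids), self.population_label, self.dosages[:, index]
        )


def _sidecar_path(map_path: Path) -> Path:
    return map_path.with_suffix(map_path.suffix + ".alleles.json")


def read_ped_map(
    ped_path: str | Path,
    map_path: str | Path,
    allele_labels: dict[str, tuple[str, str]] | None = None,
    sort: bool = False,
) -> tuple[GenotypePanel, MarkerMap]:
    """Read a PLINK-text .ped/.map pair.

    The .map has 4 whitespace columns (chromosome, id, cM ignored, bp);
    the .ped has 6 leading columns then two allele columns per marker,
    with "0" a missing allele.  A half-missing genotype (exactly one "0")
    is treated as fully missing.  The counted allele per marker is taken
    from ``allele_labels`` (marker_id -> (other, counted)), else from the
    sidecar JSON written by :func:`write_ped_map` if present, else it is
    the lexicographically second distinct allele observed.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    map_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ValueError(f"{map_path}:{lineno}: expected 4 columns, got {len(parts)}")
            map_rows.append((parts[0], parts[1], int(parts[3])))
    chroms = np.array([r[0] for r in map_rows], dtype=object)
    ids = np.array([r[1] for r in map_rows], dtype=object)
    pos = np.array([r[2] for r in map_rows], dtype=np.int64)
    if sort:
        order = np.lexsort((pos, chroms.astype(str)))
        chroms, ids, pos = chroms[order], ids[order], pos[order]
    n_markers = len(ids)

    individual_ids: list[str] = []
    pop_labels: set[str] = set()
    allele_rows_a: list[np.ndarray] = []
    allele_rows_b: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_markers:
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_markers} columns, "
                    f"got {len(parts)}"
                )
            pop_labels.add(parts[0])
            individual_ids.append(parts[1])
            alleles = parts[6:]
            bad = set(alleles) - _LEGAL_ALLELES
            if bad:
                raise ValueError(f"{ped_path}:{lineno}: illegal allele symbols {sorted(bad)}")
            allele_rows_a.append(np.array(alleles[0::2], dtype=object))
            allele_rows_b.append(np.array(alleles[1::2], dtype=object))
    if not individual_ids:
        raise ValueError(f"{ped_path}: no individuals")
    a1 = np.vstack(allele_rows_a)
    a2 = np.vstack(allele_rows_b)

    if allele_labels is None and _sidecar_path(map_path).exists():
        with open(_sidecar_path(map_path)) as fh:
            allele_labels = {k: tuple(v) for k, v in json.load(fh).items()}

    other = np.empty(n_markers, dtype=object)
    counted = np.empty(n_markers, dtype=object)
    dosages = np.full((len(individual_ids), n_markers), MISSING, dtype=np.int8)
    for m in range(n_markers):
        col1, col2 = a1[:, m], a2[:, m]
        miss = (col1 == "0") | (col2 == "0")  # half-missing -> fully missing
        observed = sorted(set(col1[~miss]) | set(col2[~miss]))
        if len(observed) > 2:
            raise ValueError(f"marker {ids[m]}: more than two alleles {observed}")
        if allele_labels is not None and ids[m] in allele_labels:
            oth, cnt = allele_labels[ids[m]]
        elif len(observed) == 2:
            oth, cnt = observed[0], observed[1]
        elif len(observed) == 1:
            oth, cnt = observed[0], observed[0]
        else:  # all missing; placeholder orientation
            oth, cnt = "0", "0"
        other[m], counted[m] = oth, cnt
        extra = (set(observed) - {oth, cnt}) if observed else set()
        if extra:
            raise ValueError(f"marker {ids[m]}: alleles {sorted(extra)} not in labels ({oth},{cnt})")
        dosages[~miss, m] = (col1[~miss] == cnt).astype(np.int8) + (
            col2[~miss] == cnt
        ).astype(np.int8)

    label = pop_labels.pop() if len(pop_labels) == 1 else "mixed"
    panel = GenotypePanel(individual_ids, label, dosages)
    mmap = MarkerMap(ids, chroms, pos, other, counted)
    return panel, mmap


def write_ped_map(
    panel: GenotypePanel,
    mmap: MarkerMap,
    ped_path: str | Path,
    map_path: str | Path,
) -> tuple[Path, Path]:
    """Write PLINK-text files plus the counted-allele JSON sidecar.

    Heterozygotes are written "other counted"; missing dosage as "0 0".
    """
    if panel.n_individuals == 0 or panel.n_markers == 0:
        raise ValueError("refusing to write an empty panel")
    if panel.n_markers != mmap.n_markers:
        raise ValueError("panel and map marker counts differ")
    ped_path, map_path = Path(ped_path), Path(map_path)
    with open(map_path, "w") as fh:
        for chrom, mid, bp in zip(mmap.chromosome, mmap.marker_id, mmap.position_bp):
            fh.write(f"{chrom}\t{mid}\t0\t{bp}\n")
    # genotype strings per dosage value, per marker
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(panel.individual_ids):
            fields = [panel.population_label, ind, "0", "0", "0", "-9"]
            row = panel.dosages[i]
            for m in range(panel.n_markers):
                d = row[m]
                oth, cnt = mmap.allele_other[m], mmap.allele_counted[m]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [oth, oth]
                elif d == 1:
                    fields += [oth, cnt]
                else:
                    fields += [cnt, cnt]
            fh.write(" ".join(fields) + "\n")
    with open(_sidecar_path(map_path), "w") as fh:
        json.dump(
            {
                mid: [oth, cnt]
                for mid, oth, cnt in zip(
                    mmap.marker_id, mmap.allele_other, mmap.allele_counted
                )
            },
            fh,
            indent=0,
            sort_keys=True,
        )
    return ped_path, map_path


#: fixed column orders per result type, used by write_table
TABLE_COLUMNS = {
    "ld": [
        "chrom", "id_i", "id_j", "pos_i", "pos_j", "dist_bp",
        "fA", "fB", "fAB", "D", "r", "r2", "n_used", "converged",
    ],
    "decay_summary": [
        "population", "bin", "n_pairs", "mean_r2", "sd_r2",
        "n_above_threshold", "pct_above_threshold",
    ],
    "phase": [
        "population_pair", "stratum", "n_pairs", "correlation_all",
        "n_pairs_highLD", "correlation_highLD", "min_r2",
    ],
    "ne": ["generations_ago", "c_morgans", "c_lo", "c_hi", "n_pairs", "mean_r2", "ne"],
    "qc_report": ["filter", "n_removed"],
}

_SORT_KEYS = {
    "ld": ["chrom", "pos_i", "pos_j"],
    "decay_summary": ["population", "bin"],
    "phase": ["population_pair", "stratum"],
    "ne": ["generations_ago"],
    "qc_report": ["filter"],
}


def write_table(rows: pd.DataFrame, path: str | Path, kind: str | None = None) -> Path:
    """Write a result table as deterministic TSV (6 significant digits)."""
    path = Path(path)
    df = rows.copy()
    if kind is not None:
        cols = TABLE_COLUMNS[kind]
        df = df[cols]
        keys = [k for k in _SORT_KEYS[kind] if k in df.columns]
        if len(df) and keys:
            df = df.sort_values(keys, kind="mergesort")
    for col in df.columns:
        if df[col].dtype.kind == "f":
            df[col] = df[col].map(lambda x: "NA" if np.isnan(x) else f"{x:.6g}")
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    return path
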