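"""Readers and writers for every external file the pipeline touches.

Formats
-------
- multi-record FASTA (protein sequences),
- PSI-BLAST ASCII PSSM (the ``-Q`` checkpoint text dialect),
- tab-separated per-residue annotation tables
  (``protein_id  position  disorder  ss  sa``),
- tab-separated site tables (``protein_id  position  label``),
- tab-separated feature matrices with a feature-catalog header.

All positions in files are 1-based inclusive. All tabular formats are
tab-separated with a fixed header row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .constants import AMINO_ACIDS, PSIBLAST_COLUMN_ORDER, SA_STATES, SS_STATES

_AA_SET = set(AMINO_ACIDS)

# permutation taking PSI-BLAST column order -> alphabetical order
_PSIBLAST_TO_ALPHA = np.array(
    [PSIBLAST_COLUMN_ORDER.index(aa) for aa in AMINO_ACIDS]
)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its identifier.

    The sequence is uppercase over the 20 standard amino-acid letters;
    non-standard letters (B, Z, U, X, ...) are rejected at parse time since
    silent coercion would corrupt composition-based features.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise ValueError(
                f"protein {self.id!r}: non-standard residue letter(s) "
                f"{sorted(bad)}; only the 20 standard amino acids are accepted"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ResidueAnnotations:
    """Per-residue annotation tracks for one protein.

    Attributes
    ----------
    protein_id : str
    pssm : (L, 20) float array or None
        Conservation profile, columns in alphabetical amino-acid order,
        values in [0, 1] (weighted percentages / 100). May be attached
        after construction via :func:`attach_pssm`.
    disorder : (L,) float array
        Disorder propensity per residue, in [0, 1].
    ss : list of str
        3-state secondary structure per residue: helix / strand / other.
    sa : list of str
        2-state solvent accessibility per residue: buried / exposed.
    """

    protein_id: str
    disorder: np.ndarray
    ss: list[str]
    sa: list[str]
    pssm: np.ndarray | None = field(default=None)

    def __len__(self) -> int:
        return len(self.disorder)

    def validate(self, sequence_length: int | None = None) -> None:
        n = len(self.disorder)
        if not (len(self.ss) == len(self.sa) == n):
            raise ValueError(
                f"{self.protein_id}: annotation tracks have unequal lengths"
            )
        if sequence_length is not None and n != sequence_length:
            raise ValueError(
                f"{self.protein_id}: annotation length {n} != "
                f"sequence length {sequence_length}"
            )
        if np.any((self.disorder < 0) | (self.disorder > 1)):
            raise ValueError(f"{self.protein_id}: disorder outside [0, 1]")
        if self.pssm is not None and self.pssm.shape != (n, 20):
            raise ValueError(
                f"{self.protein_id}: PSSM shape {self.pssm.shape} != ({n}, 20)"
            )


@dataclass(frozen=True)
class SiteAnnotation:
    """One labeled serine position (1-based) in a protein."""

    protein_id: str
    position: int
    label: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative"):
            raise ValueError(f"unknown site label {self.label!r}")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects.

    The id is the header token before the first whitespace. Raises on an
    empty file, duplicate ids, or non-amino-acid sequence characters (the
    error names the offending line).
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        bad = set(seq) - _AA_SET
        if bad:
            lineno = _find_offending_line(path, bad)
            raise ValueError(
                f"{path}:{lineno}: invalid sequence character(s) "
                f"{sorted(bad)} in record {rec.id!r}"
            )
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def _find_offending_line(path: Path, bad_chars: set[str]) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) & bad_chars:
                return i
    return 0


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write protein records as FASTA, 60 columns per sequence line."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def read_pssm_ascii(
    path: str | Path,
    expected_length: int,
    values: str = "percentages",
) -> np.ndarray:
    """Read a PSI-BLAST ASCII PSSM into an (L, 20) track.

    Parameters
    ----------
    path : path
        File in the PSI-BLAST ``-Q`` ASCII layout: header lines, then one
        row per residue carrying 20 log-odds columns followed by 20
        weighted-percentage columns.
    expected_length : int
        Number of residues the protein has; a row-count mismatch raises.
    values : {"percentages", "log_odds"}
        Which block to return. The default returns the weighted-percentage
        columns divided by 100, i.e. per-residue substitution probabilities
        in [0, 1]. ``log_odds`` returns the raw log-odds scores instead.

    Returns
    -------
    (L, 20) float array with columns in alphabetical amino-acid order.
    """
    if values not in ("percentages", "log_odds"):
        raise ValueError(f"values must be 'percentages' or 'log_odds', got {values!r}")
    path = Path(path)
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            # data rows start with the 1-based residue index then the residue
            if len(tokens) < 42 or not tokens[0].isdigit():
                continue
            try:
                scores = np.array([float(t) for t in tokens[2:42]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable PSSM row") from exc
            rows.append(scores)
    if len(rows) != expected_length:
        raise ValueError(
            f"{path}: PSSM has {len(rows)} residue rows, expected {expected_length}"
        )
    data = np.vstack(rows)
    block = data[:, 20:40] / 100.0 if values == "percentages" else data[:, 0:20]
    return block[:, _PSIBLAST_TO_ALPHA]


def write_pssm_ascii(
    sequence: str,
    log_odds: np.ndarray,
    percentages: np.ndarray,
    path: str | Path,
) -> None:
    """Write a PSSM in the PSI-BLAST ASCII dialect.

    Inputs are (L, 20) arrays with columns in alphabetical order;
    ``percentages`` holds integers 0..100. The writer emits the PSI-BLAST
    column order so the file round-trips through :func:`read_pssm_ascii`.
    """
    L = len(sequence)
    if log_odds.shape != (L, 20) or percentages.shape != (L, 20):
        raise ValueError("PSSM arrays must be (L, 20)")
    alpha_to_psiblast = np.array(
        [AMINO_ACIDS.index(aa) for aa in PSIBLAST_COLUMN_ORDER]
    )
    lo = log_odds[:, alpha_to_psiblast]
    pc = percentages[:, alpha_to_psiblast]
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted "
            "observed percentages rounded down, information per position, "
            "and relative weight of gapless real matches to pseudocounts\n"
        )
        header = " ".join(f"{aa:>3}" for aa in PSIBLAST_COLUMN_ORDER)
        fh.write(f"          {header}  {header}\n")
        for i in range(L):
            lo_s = " ".join(f"{int(round(v)):>3d}" for v in lo[i])
            pc_s = " ".join(f"{int(round(v)):>3d}" for v in pc[i])
            fh.write(f"{i + 1:>5d} {sequence[i]} {lo_s}  {pc_s}  0.00 0.00\n")


def read_annotation_table(path: str | Path) -> dict[str, ResidueAnnotations]:
    """Read a per-residue annotation table into per-protein tracks.

    Expects a tab-separated file with header
    ``protein_id  position  disorder  ss  sa``; positions per protein must
    be contiguous from 1. Returns a dict keyed by protein id; the PSSM slot
    of each :class:`ResidueAnnotations` is left empty (attach separately).
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = ["protein_id", "position", "disorder", "ss", "sa"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")

    bad_dis = df.index[(df["disorder"] < 0) | (df["disorder"] > 1)]
    if len(bad_dis):
        raise ValueError(
            f"{path}: disorder outside [0, 1] at data row {bad_dis[0] + 1}"
        )
    bad_ss = df.index[~df["ss"].isin(SS_STATES)]
    if len(bad_ss):
        raise ValueError(
            f"{path}: unknown ss label {df['ss'].iloc[bad_ss[0]]!r} "
            f"at data row {bad_ss[0] + 1}"
        )
    bad_sa = df.index[~df["sa"].isin(SA_STATES)]
    if len(bad_sa):
        raise ValueError(
            f"{path}: unknown sa label {df['sa'].iloc[bad_sa[0]]!r} "
            f"at data row {bad_sa[0] + 1}"
        )

    out: dict[str, ResidueAnnotations] = {}
    for pid, grp in df.groupby("protein_id", sort=False):
        grp = grp.sort_values("position")
        positions = grp["position"].to_numpy()
        expected = np.arange(1, len(grp) + 1)
        if not np.array_equal(positions, expected):
            raise ValueError(
                f"{path}: protein {pid!r} positions are not contiguous "
                f"from 1 (gap or duplicate)"
            )
        out[str(pid)] = ResidueAnnotations(
            protein_id=str(pid),
            disorder=grp["disorder"].to_numpy(dtype=float),
            ss=list(grp["ss"]),
            sa=list(grp["sa"]),
        )
    return out


def write_annotation_table(
    annotations: Mapping[str, ResidueAnnotations], path: str | Path
) -> None:
    """Write per-residue disorder/ss/sa tracks as a TSV annotation table."""
    rows = []
    for pid, ann in annotations.items():
        for i in range(len(ann)):
            rows.append((pid, i + 1, ann.disorder[i], ann.ss[i], ann.sa[i]))
    df = pd.DataFrame(rows, columns=["protein_id", "position", "disorder", "ss", "sa"])
    df.to_csv(path, sep="\t", index=False)


def attach_pssm(
    annotations: ResidueAnnotations, pssm: np.ndarray
) -> ResidueAnnotations:
    """Attach a PSSM track, validating its shape against the other tracks."""
    annotations.pssm = np.asarray(pssm, dtype=float)
    annotations.validate()
    return annotations


def read_site_table(path: str | Path) -> list[SiteAnnotation]:
    """Read a TSV site table (``protein_id  position  label``)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = ["protein_id", "position", "label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return [
        SiteAnnotation(str(r.protein_id), int(r.position), str(r.label))
        for r in df.itertuples(index=False)
    ]


def write_site_table(sites: Iterable[SiteAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.protein_id, s.position, s.label) for s in sites],
        columns=["protein_id", "position", "label"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_feature_matrix(matrix, path: str | Path) -> None:
    """Write a :class:`~pyruvoylsite.features.FeatureMatrix` as TSV.

    Layout: header row ``sample_id  label  <feature names...>``, one row per
    sample. Values are written at full precision so read-back is exact.
    """
    if matrix.n_samples == 0:
        raise ValueError("refusing to write an empty feature matrix")
    if matrix.values.shape[1] != len(matrix.catalog):
        raise ValueError(
            f"matrix width {matrix.values.shape[1]} != catalog size "
            f"{len(matrix.catalog)}"
        )
    df = pd.DataFrame(matrix.values, columns=matrix.catalog.names())
    df.insert(0, "label", matrix.labels)
    df.insert(0, "sample_id", matrix.sample_ids)
    df.to_csv(path, sep="\t", index=False, float_format=None)


def read_feature_matrix(path: str | Path):
    """Read a TSV feature matrix written by :func:`write_feature_matrix`."""
    from .features import FeatureCatalog, FeatureMatrix

    df = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str}, float_precision="round_trip"
    )
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty feature matrix")
    names = list(df.columns[2:])
    catalog = FeatureCatalog.from_names(names)
    return FeatureMatrix(
        sample_ids=list(df["sample_id"]),
        labels=df["label"].to_numpy(dtype=int),
        values=df[names].to_numpy(dtype=float),
        catalog=catalog,
    )
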