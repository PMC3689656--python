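"""Six-track feature encoding of serine-centered peptide windows.

A (2w+1)-residue window is encoded into 64w + 26 features:

====================  =============  ====================================
family                count          value per site
====================  =============  ====================================
pssm                  20 * (2w+1)    substitution probability per target
                                     amino acid, from the PSSM track
disorder              1 * (2w+1)     disorder propensity in [0, 1]
ss                    3 * (2w+1)     secondary-structure one-hot
                                     (helix=100, strand=010, other=001)
sa                    2 * (2w+1)     solvent-accessibility one-hot
                                     (buried=10, exposed=01)
aaf                   5 * 2w         Atchley amino-acid factors
                                     (center excluded: always serine)
freq                  1 * 2w         positional occurrence frequency of
                                     the symbol the window carries
                                     (center excluded)
====================  =============  ====================================

Padded ('X') sites contribute zeros to pssm/disorder/ss/sa/aaf; the freq
feature uses the learned frequency of 'X' itself at that offset. Site
offsets are 1-based within the window (center = w + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .constants import (
    AMINO_ACIDS,
    ATCHLEY_FACTOR_NAMES,
    ATCHLEY_FACTORS,
    PAD,
    SA_ONEHOT,
    SA_STATES,
    SS_ONEHOT,
    SS_STATES,
    WINDOW_ALPHABET,
)
from .io import ResidueAnnotations
from .windowing import PeptideWindow, WindowConfig

FAMILIES = ("pssm", "disorder", "ss", "sa", "aaf", "freq")


@dataclass(frozen=True)
class FeatureDescriptor:
    """Provenance of one feature: family, window offset, and detail.

    ``detail`` is the target amino acid (pssm), the structure or
    accessibility state (ss/sa), the Atchley factor name (aaf), or empty
    (disorder/freq).
    """

    family: str
    offset: int  # 1-based site index within the window
    detail: str = ""

    @property
    def name(self) -> str:
        if self.detail:
            return f"{self.family}|o{self.offset}|{self.detail}"
        return f"{self.family}|o{self.offset}"

    @classmethod
    def from_name(cls, name: str) -> "FeatureDescriptor":
        parts = name.split("|")
        if len(parts) not in (2, 3) or not parts[1].startswith("o"):
            raise ValueError(f"malformed feature name {name!r}")
        return cls(
            family=parts[0],
            offset=int(parts[1][1:]),
            detail=parts[2] if len(parts) == 3 else "",
        )


@dataclass(frozen=True)
class FeatureCatalog:
    """Ordered, unique feature descriptors for one window geometry."""

    descriptors: tuple[FeatureDescriptor, ...]

    def __len__(self) -> int:
        return len(self.descriptors)

    def __iter__(self):
        return iter(self.descriptors)

    def __getitem__(self, i: int) -> FeatureDescriptor:
        return self.descriptors[i]

    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def index_of(self, name: str) -> int:
        try:
            return self.names().index(name)
        except ValueError:
            raise KeyError(f"feature {name!r} not in catalog") from None

    def family_counts(self) -> dict[str, int]:
        counts = {f: 0 for f in FAMILIES}
        for d in self.descriptors:
            counts[d.family] += 1
        return counts

    @classmethod
    def from_names(cls, names: Sequence[str]) -> "FeatureCatalog":
        return cls(tuple(FeatureDescriptor.from_name(n) for n in names))


def build_catalog(config: WindowConfig) -> FeatureCatalog:
    """Build the 64w + 26 feature catalog for a window geometry.

    Order: family (pssm, disorder, ss, sa, aaf, freq), then window offset,
    then detail alphabetical.
    """
    w = config.w
    n = config.window_length
    center = w + 1
    descriptors: list[FeatureDescriptor] = []
    for off in range(1, n + 1):
        for aa in AMINO_ACIDS:
            descriptors.append(FeatureDescriptor("pssm", off, aa))
    for off in range(1, n + 1):
        descriptors.append(FeatureDescriptor("disorder", off))
    for off in range(1, n + 1):
        for state in SS_STATES:
            descriptors.append(FeatureDescriptor("ss", off, state))
    for off in range(1, n + 1):
        for state in SA_STATES:
            descriptors.append(FeatureDescriptor("sa", off, state))
    for off in range(1, n + 1):
        if off == center:
            continue
        for factor in ATCHLEY_FACTOR_NAMES:
            descriptors.append(FeatureDescriptor("aaf", off, factor))
    for off in range(1, n + 1):
        if off == center:
            continue
        descriptors.append(FeatureDescriptor("freq", off))
    catalog = FeatureCatalog(tuple(descriptors))
    assert len(catalog) == 64 * w + 26
    return catalog


@dataclass(frozen=True)
class PositionFrequencyTable:
    """Per-offset symbol frequencies learned from training windows.

    ``table`` maps window offset (1-based, center excluded) to a dict over
    the 21 window symbols (20 amino acids + 'X') summing to 1.
    """

    w: int
    table: Mapping[int, Mapping[str, float]]

    def frequency(self, offset: int, symbol: str) -> float:
        if offset not in self.table:
            raise KeyError(f"offset {offset} not in frequency table")
        return self.table[offset].get(symbol, 0.0)


def fit_frequency_table(
    windows: Sequence[PeptideWindow],
    config: WindowConfig,
    on: str = "positives",
) -> PositionFrequencyTable:
    """Learn per-offset symbol occurrence frequencies from training windows.

    By default only positive training windows are counted, giving the
    positional composition that characterizes pyruvoyl sites; ``on="all"``
    counts every training window instead.
    """
    if on not in ("positives", "all"):
        raise ValueError(f"on must be 'positives' or 'all', got {on!r}")
    pool = [x for x in windows if x.is_positive] if on == "positives" else list(windows)
    if not pool:
        raise ValueError("no positive training windows to fit frequencies on")
    n = config.window_length
    center = config.w + 1
    for x in pool:
        if len(x.residues) != n:
            raise ValueError(
                f"window {x.sample_id()} has length {len(x.residues)}, "
                f"config expects {n}"
            )
    table: dict[int, dict[str, float]] = {}
    for off in range(1, n + 1):
        if off == center:
            continue
        counts = {sym: 0 for sym in WINDOW_ALPHABET}
        for x in pool:
            counts[x.residues[off - 1]] += 1
        total = len(pool)
        table[off] = {sym: c / total for sym, c in counts.items()}
    return PositionFrequencyTable(w=config.w, table=table)


@dataclass
class FeatureMatrix:
    """Encoded samples aligned to a :class:`FeatureCatalog`."""

    sample_ids: list[str]
    labels: np.ndarray  # 1 = positive, 0 = negative
    values: np.ndarray  # (n_samples, n_features)
    catalog: FeatureCatalog

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.sample_ids),
            len(self.catalog),
        ):
            raise ValueError(
                f"value grid {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.catalog)} features"
            )
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")


def encode_window(
    window: PeptideWindow,
    annotations: ResidueAnnotations,
    freq: PositionFrequencyTable,
    catalog: FeatureCatalog,
) -> np.ndarray:
    """Encode one window into a feature row aligned to ``catalog``."""
    config = WindowConfig(w=window.w)
    if freq.w != config.w:
        raise ValueError("frequency table was fit for a different window width")
    if annotations.pssm is None:
        raise ValueError(
            f"{annotations.protein_id}: PSSM track not attached to annotations"
        )
    L = len(annotations)
    center = config.w + 1
    row = np.zeros(len(catalog))
    for j, d in enumerate(catalog):
        # absolute 1-based residue position this offset points at
        pos = window.center_pos + (d.offset - center)
        padded = not (1 <= pos <= L)
        residue = window.residues[d.offset - 1]
        if padded != (residue == PAD):
            raise ValueError(
                f"{window.sample_id()}: annotation track does not cover "
                f"window offset {d.offset}"
            )
        if d.family == "freq":
            row[j] = freq.frequency(d.offset, residue)
            continue
        if padded:
            row[j] = 0.0
            continue
        i = pos - 1
        if d.family == "pssm":
            row[j] = annotations.pssm[i, AMINO_ACIDS.index(d.detail)]
        elif d.family == "disorder":
            row[j] = annotations.disorder[i]
        elif d.family == "ss":
            row[j] = SS_ONEHOT[annotations.ss[i]][d.detail]
        elif d.family == "sa":
            row[j] = SA_ONEHOT[annotations.sa[i]][d.detail]
        elif d.family == "aaf":
            row[j] = ATCHLEY_FACTORS[residue][d.detail]
        else:  # pragma: no cover
            raise ValueError(f"unknown feature family {d.family!r}")
    return row


def encode_all(
    windows: Sequence[PeptideWindow],
    annotations: Mapping[str, ResidueAnnotations],
    freq: PositionFrequencyTable,
    catalog: FeatureCatalog,
) -> FeatureMatrix:
    """Encode a window list into a :class:`FeatureMatrix` (order preserved)."""
    if not windows:
        raise ValueError("no windows to encode")
    rows = []
    for x in windows:
        if x.protein_id not in annotations:
            raise ValueError(
                f"{x.sample_id()}: no annotations for protein {x.protein_id!r}"
            )
        try:
            rows.append(encode_window(x, annotations[x.protein_id], freq, catalog))
        except Exception as exc:
            raise ValueError(f"failed to encode sample {x.sample_id()}") from exc
    return FeatureMatrix(
        sample_ids=[x.sample_id() for x in windows],
        labels=np.array([1 if x.is_positive else 0 for x in windows]),
        values=np.vstack(rows),
        catalog=catalog,
    )
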