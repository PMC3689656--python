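"""Serine-centered peptide window extraction.

Every serine in a protein yields exactly one window of length 2w+1 (w
residues on each side of the serine). Windows that run off either end of
the protein are padded with ``'X'``. A window is labeled positive when its
center position carries an annotated pyruvoyl-forming serine; every other
serine is a negative ("non-observed" sites are negatives -- there is no
unknown class).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .constants import PAD
from .io import ProteinRecord, SiteAnnotation


@dataclass(frozen=True)
class WindowConfig:
    """Window geometry: half-width ``w``, window length ``2w + 1``."""

    w: int

    def __post_init__(self) -> None:
        if self.w < 1:
            raise ValueError(f"window half-width must be >= 1, got {self.w}")

    @property
    def window_length(self) -> int:
        return 2 * self.w + 1

    @classmethod
    def from_length(cls, window_length: int) -> "WindowConfig":
        if window_length < 3 or window_length % 2 == 0:
            raise ValueError(
                f"window length must be odd and >= 3, got {window_length}"
            )
        return cls(w=(window_length - 1) // 2)


@dataclass(frozen=True)
class PeptideWindow:
    """A labeled (2w+1)-mer centered on a serine.

    ``center_pos`` is the 1-based position of the serine in the source
    protein; ``residues`` is the window string over the 20 amino acids plus
    'X', with 'X' only in maximal runs at the ends.
    """

    protein_id: str
    center_pos: int
    residues: str
    label: str  # "positive" | "negative"

    @property
    def w(self) -> int:
        return (len(self.residues) - 1) // 2

    @property
    def is_positive(self) -> bool:
        return self.label == "positive"

    def sample_id(self) -> str:
        return f"{self.protein_id}:{self.center_pos}"


def write_window_table(windows: Sequence[PeptideWindow], path) -> None:
    """Write windows as TSV (protein_id, center_pos, residues, label)."""
    import pandas as pd

    pd.DataFrame(
        [(x.protein_id, x.center_pos, x.residues, x.label) for x in windows],
        columns=["protein_id", "center_pos", "residues", "label"],
    ).to_csv(path, sep="\t", index=False)


def read_window_table(path) -> list[PeptideWindow]:
    """Read a TSV window table written by :func:`write_window_table`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "residues": str})
    return [
        PeptideWindow(str(r.protein_id), int(r.center_pos), str(r.residues), str(r.label))
        for r in df.itertuples(index=False)
    ]


def extract_windows(
    protein: ProteinRecord,
    positives: Iterable[int],
    config: WindowConfig,
) -> list[PeptideWindow]:
    """Extract one window per serine of ``protein``.

    Parameters
    ----------
    protein : ProteinRecord
    positives : iterable of int
        1-based positions of annotated pyruvoyl serines in this protein.
        Every listed position must index a serine.
    config : WindowConfig

    Returns
    -------
    Windows in ascending center position; center residue is always 'S'.
    """
    seq = protein.sequence
    L = len(seq)
    pos_set = set(positives)
    for p in pos_set:
        if not (1 <= p <= L):
            raise ValueError(
                f"{protein.id}: positive position {p} out of bounds (1..{L})"
            )
        if seq[p - 1] != "S":
            raise ValueError(
                f"{protein.id}: annotated positive at position {p} is "
                f"{seq[p - 1]!r}, not a serine"
            )
    w = config.w
    windows: list[PeptideWindow] = []
    for p in range(1, L + 1):
        if seq[p - 1] != "S":
            continue
        chunk = []
        for i in range(p - w, p + w + 1):
            chunk.append(seq[i - 1] if 1 <= i <= L else PAD)
        windows.append(
            PeptideWindow(
                protein_id=protein.id,
                center_pos=p,
                residues="".join(chunk),
                label="positive" if p in pos_set else "negative",
            )
        )
    return windows


def build_sample_set(
    proteins: Sequence[ProteinRecord],
    sites: Sequence[SiteAnnotation],
    config: WindowConfig,
) -> list[PeptideWindow]:
    """Extract windows for a whole protein set.

    Concatenates per-protein extractions in protein order (then ascending
    position), so downstream seeded sampling is reproducible. Site records
    labeled positive mark pyruvoyl serines; sites referencing unknown
    proteins raise.
    """
    known = {p.id for p in proteins}
    by_protein: dict[str, set[int]] = {}
    for s in sites:
        if s.protein_id not in known:
            raise ValueError(f"site references unknown protein {s.protein_id!r}")
        if s.label == "positive":
            by_protein.setdefault(s.protein_id, set()).add(s.position)
    out: list[PeptideWindow] = []
    for protein in proteins:
        out.extend(extract_windows(protein, by_protein.get(protein.id, ()), config))
    return out
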