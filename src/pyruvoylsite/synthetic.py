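"""Download-free synthetic inputs with controllable planted signal.

The generator emulates the shape of a curated pyruvoyl-serine corpus --
a few dozen proteins, one annotated autocatalytic serine each, several
hundred background serines -- together with every per-residue annotation
track the pipeline consumes (PSSM conservation profile, disorder score,
3-state secondary structure, 2-state solvent accessibility). It writes
the same file formats the real-data path reads (FASTA, TSV site and
annotation tables, PSI-BLAST ASCII PSSMs), so both paths share one
reader.

Signal is planted around the annotated serine, mirroring what is known
about self-processing sites: a glycine bias immediately before the
nucleophile, sharply conserved PSSM columns at fixed offsets, and
beta-strand / buried enrichment nearby. There are six hallmark signals
(three conserved columns, one strand, two buried), each mapping to one
known feature descriptor recorded in the manifest so recovery can be
measured. Real pyruvoyl enzymes are structurally heterogeneous, so each
planted site expresses only a random subset of the hallmarks
(``signals_per_site`` of the six): no tiny feature subset suffices to
recognize every site, and a recovery run must assemble most of the
planted set. Setting the "positive" probabilities equal to background
(:meth:`SyntheticConfig.zero_signal`) yields a null corpus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .constants import AMINO_ACIDS, BACKGROUND_AA_FREQS
from .io import (
    ProteinRecord,
    ResidueAnnotations,
    SiteAnnotation,
    attach_pssm,
    write_annotation_table,
    write_fasta,
    write_pssm_ascii,
    write_site_table,
)
from .windowing import WindowConfig, build_sample_set


#: conserved PSSM columns planted at offsets relative to the serine
PLANTED_CONSERVATION: dict[int, str] = {-1: "G", 2: "L", 3: "I"}
#: beta-strand enrichment offset relative to the serine
PLANTED_STRAND_OFFSET: int = -2
#: buried-residue enrichment offsets relative to the serine
PLANTED_BURIED_OFFSETS: tuple[int, ...] = (-1, 1)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator knobs; defaults emulate the study corpus shape.

    46 proteins of 110-170 residues with one planted site each yield
    roughly 400 background serines (~6.6% serine composition), i.e. about
    46 positive and 400 negative windows.
    """

    n_proteins: int = 46
    length_range: tuple[int, int] = (110, 170)
    n_positive_sites: int = 46
    #: how many of the six hallmark signals each planted site expresses
    #: (always including at least one conserved column: conservation is
    #: the universal hallmark of autocatalytic sites)
    signals_per_site: int = 3
    #: probability that a planted-offset PSSM column is peaked at its
    #: target amino acid, when that hallmark is expressed vs anywhere else
    conservation_prob_pos: float = 1.0
    conservation_prob_bg: float = 0.005
    #: probability the residue preceding the serine is glycine when the
    #: -1 conservation hallmark is expressed (conserved columns peak at
    #: the wild-type residue)
    g_bias: float = 0.75
    #: beta-strand probability at the planted offset when expressed,
    #: vs background
    strand_prob_pos: float = 1.0
    strand_prob_bg: float = 0.10
    helix_prob_bg: float = 0.35
    #: buried probability at the planted offsets when expressed,
    #: vs background
    buried_prob_pos: float = 1.0
    buried_prob_bg: float = 0.15
    #: disorder Beta(a, b) parameters, background and near planted strands
    disorder_shape_bg: tuple[float, float] = (2.0, 4.0)
    disorder_shape_pos: tuple[float, float] = (1.7, 4.5)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.conservation_prob_pos,
            self.conservation_prob_bg,
            self.g_bias,
            self.strand_prob_pos,
            self.strand_prob_bg,
            self.helix_prob_bg,
            self.buried_prob_pos,
            self.buried_prob_bg,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.n_positive_sites > self.n_proteins:
            raise ValueError("at most one planted site per protein")
        if not (1 <= self.signals_per_site <= 6):
            raise ValueError("signals_per_site must be in 1..6")
        lo, hi = self.length_range
        if lo < 30 or hi < lo:
            raise ValueError("length range must satisfy 30 <= lo <= hi")

    def zero_signal(self) -> "SyntheticConfig":
        """Copy with every planted probability collapsed to background."""
        return SyntheticConfig(
            n_proteins=self.n_proteins,
            length_range=self.length_range,
            n_positive_sites=self.n_positive_sites,
            signals_per_site=self.signals_per_site,
            conservation_prob_pos=self.conservation_prob_bg,
            conservation_prob_bg=self.conservation_prob_bg,
            g_bias=BACKGROUND_AA_FREQS[AMINO_ACIDS.index("G")],
            strand_prob_pos=self.strand_prob_bg,
            strand_prob_bg=self.strand_prob_bg,
            helix_prob_bg=self.helix_prob_bg,
            buried_prob_pos=self.buried_prob_bg,
            buried_prob_bg=self.buried_prob_bg,
            disorder_shape_pos=self.disorder_shape_bg,
            disorder_shape_bg=self.disorder_shape_bg,
            seed=self.seed,
        )


@dataclass
class FixtureBundle:
    """Generated corpus: in-memory objects, manifest, and optional files."""

    proteins: list[ProteinRecord]
    sites: list[SiteAnnotation]
    annotations: dict[str, ResidueAnnotations]
    manifest: dict
    paths: dict[str, Path] = field(default_factory=dict)

    def planted_feature_names(self, config: WindowConfig) -> list[str]:
        """Catalog feature names of the planted signals for one geometry."""
        center = config.w + 1
        names = []
        for rel, aa in sorted(PLANTED_CONSERVATION.items()):
            names.append(f"pssm|o{center + rel}|{aa}")
        names.append(f"ss|o{center + PLANTED_STRAND_OFFSET}|strand")
        for rel in PLANTED_BURIED_OFFSETS:
            names.append(f"sa|o{center + rel}|buried")
        return names


def _peaked_column(rng: np.random.Generator, target: int) -> np.ndarray:
    p = 0.15 * rng.dirichlet(np.ones(20))
    p[target] += 0.85
    return p / p.sum()


def _background_column(rng: np.random.Generator, own: int) -> np.ndarray:
    p = 0.5 * rng.dirichlet(np.ones(20))
    p[own] += 0.5
    return p / p.sum()


def generate(config: SyntheticConfig, out_dir: str | Path | None = None) -> FixtureBundle:
    """Generate a synthetic corpus; optionally write it to ``out_dir``.

    Deterministic under ``config.seed``: the same config yields
    byte-identical files. All generated files parse with
    :mod:`pyruvoylsite.io`.
    """
    rng = np.random.default_rng(config.seed)
    aa = np.array(list(AMINO_ACIDS))
    g_idx = AMINO_ACIDS.index("G")
    s_idx = AMINO_ACIDS.index("S")

    proteins: list[ProteinRecord] = []
    sites: list[SiteAnnotation] = []
    annotations: dict[str, ResidueAnnotations] = {}
    planted: dict[str, int] = {}

    for i in range(config.n_proteins):
        pid = f"SYN{i + 1:04d}"
        L = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        seq = rng.choice(20, size=L, p=BACKGROUND_AA_FREQS)

        site: int | None = None
        expressed: np.ndarray | None = None
        if i < config.n_positive_sites:
            # site may sit close enough to a terminus for window padding,
            # but planted offsets (-2..+3) always stay in-sequence
            site = int(rng.integers(4, L - 2))  # 1-based, in [4, L-3]
            seq[site - 1] = s_idx
            # hallmarks 0..2: conserved columns (offsets sorted), 3: strand,
            # 4..5: buried offsets -- each site expresses a random subset
            # containing at least one conserved column
            while True:
                expressed = np.zeros(6, dtype=bool)
                chosen = rng.choice(6, size=config.signals_per_site, replace=False)
                expressed[chosen] = True
                if expressed[:3].any():
                    break
            if expressed[0] and rng.random() < config.g_bias:
                seq[site - 2] = g_idx
        sequence = "".join(aa[seq])

        pssm = np.empty((L, 20))
        for r in range(L):
            pssm[r] = _background_column(rng, int(seq[r]))
        disorder = rng.beta(*config.disorder_shape_bg, size=L)
        ss_draw = rng.random(L)
        ss = np.where(
            ss_draw < config.strand_prob_bg,
            "strand",
            np.where(ss_draw < config.strand_prob_bg + config.helix_prob_bg, "helix", "other"),
        ).tolist()
        sa = np.where(rng.random(L) < config.buried_prob_bg, "buried", "exposed").tolist()

        if site is not None:
            assert expressed is not None
            for h, (rel, target) in enumerate(sorted(PLANTED_CONSERVATION.items())):
                pos = site + rel
                prob = (
                    config.conservation_prob_pos
                    if expressed[h]
                    else config.conservation_prob_bg
                )
                if rng.random() < prob:
                    pssm[pos - 1] = _peaked_column(rng, AMINO_ACIDS.index(target))
            pos = site + PLANTED_STRAND_OFFSET
            prob = config.strand_prob_pos if expressed[3] else config.strand_prob_bg
            ss[pos - 1] = "strand" if rng.random() < prob else "other"
            for h, rel in enumerate(PLANTED_BURIED_OFFSETS):
                pos = site + rel
                prob = config.buried_prob_pos if expressed[4 + h] else config.buried_prob_bg
                sa[pos - 1] = "buried" if rng.random() < prob else "exposed"
            for rel in range(-2, 4):
                disorder[site + rel - 1] = rng.beta(*config.disorder_shape_pos)

        protein = ProteinRecord(id=pid, sequence=sequence)
        ann = ResidueAnnotations(
            protein_id=pid, disorder=disorder, ss=ss, sa=sa
        )
        attach_pssm(ann, pssm)
        proteins.append(protein)
        annotations[pid] = ann
        if site is not None:
            sites.append(SiteAnnotation(pid, site, "positive"))
            planted[pid] = site

    n_serines = sum(p.sequence.count("S") for p in proteins)
    manifest = {
        "config": asdict(config),
        "planted_sites": planted,
        "planted_relative_features": {
            "pssm": {str(k): v for k, v in PLANTED_CONSERVATION.items()},
            "strand_offset": PLANTED_STRAND_OFFSET,
            "buried_offsets": list(PLANTED_BURIED_OFFSETS),
        },
        "n_serines": n_serines,
        "n_positive": len(planted),
        "n_negative": n_serines - len(planted),
    }
    bundle = FixtureBundle(
        proteins=proteins, sites=sites, annotations=annotations, manifest=manifest
    )
    if out_dir is not None:
        bundle.paths = _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: FixtureBundle, out_dir: Path) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    pssm_dir = out_dir / "pssm"
    pssm_dir.mkdir(exist_ok=True)
    paths = {
        "fasta": out_dir / "proteins.fasta",
        "sites": out_dir / "sites.tsv",
        "annotations": out_dir / "annotations.tsv",
        "pssm_dir": pssm_dir,
        "manifest": out_dir / "manifest.json",
    }
    write_fasta(bundle.proteins, paths["fasta"])
    write_site_table(bundle.sites, paths["sites"])
    write_annotation_table(bundle.annotations, paths["annotations"])
    for protein in bundle.proteins:
        ann = bundle.annotations[protein.id]
        percentages = np.round(ann.pssm * 100.0)
        # crude integer log-odds consistent with the percentage block
        log_odds = np.round(
            2.0 * np.log2((ann.pssm + 0.01) / BACKGROUND_AA_FREQS[None, :])
        )
        write_pssm_ascii(
            protein.sequence, log_odds, percentages, pssm_dir / f"{protein.id}.pssm"
        )
    with open(paths["manifest"], "w") as fh:
        json.dump(bundle.manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def partition_sizes(n: int, parts: int) -> list[int]:
    """Near-equal part sizes, larger parts first (e.g. 407/4 -> [102,102,102,101])."""
    base, rem = divmod(n, parts)
    return [base + (1 if p < rem else 0) for p in range(parts)]


def expected_counts(bundle: FixtureBundle, config: WindowConfig, parts: int = 4) -> dict:
    """Exact expected window/class/dataset counts for test assertions."""
    windows = build_sample_set(bundle.proteins, bundle.sites, config)
    n_pos = sum(1 for x in windows if x.is_positive)
    n_neg = len(windows) - n_pos
    return {
        "n_windows": len(windows),
        "n_positive": n_pos,
        "n_negative": n_neg,
        "part_sizes": partition_sizes(n_neg, parts),
        "dataset_sizes": [n_pos + s for s in partition_sizes(n_neg, parts)],
        "window_length": config.window_length,
    }
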