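"""NMR interaction mapping for an intrinsically disordered protein segment.

Two per-residue observables are computed from titration peak tables of a
uniformly labelled protein before and after addition of an unlabelled
binding partner:

* the amide intensity ratio I/I0 (partner added / free), whose attenuation
  below 1 marks residues in intermediate exchange, i.e. residues involved
  in the interaction;
* the secondary C-alpha chemical shift (chemical shift index)
  ``ddCA = dCA(observed) - dCA(random coil)``, whose near-zero values
  indicate a disordered backbone.

Contiguous stretches of attenuated residues are merged into interaction
region calls, bridging short gaps caused by prolines (which have no
backbone amide) or unassigned residues.

Residue numbers are 1-based and counted from the first start codon of the
open reading frame, matching the convention of the yeast Rad52 literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PeakTable",
    "RandomCoilModel",
    "RegionCall",
    "intensity_ratio",
    "secondary_shift",
    "disorder_flag",
    "call_interaction_region",
    "read_fasta",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Random-coil C-alpha chemical shifts (ppm, DSS-referenced) for the 20
# standard amino acids, from the Wishart et al. (1995) peptide reference
# set, with a uniform -2.0 ppm correction applied to residues that precede
# a proline.  The table is replaceable via RandomCoilModel.from_csv.
_WISHART_CA = {
    "A": 52.5, "C": 58.2, "D": 54.2, "E": 56.6, "F": 57.7,
    "G": 45.1, "H": 55.0, "I": 61.1, "K": 56.2, "L": 55.1,
    "M": 55.4, "N": 53.1, "P": 63.3, "Q": 55.7, "R": 56.0,
    "S": 58.3, "T": 61.8, "V": 62.2, "W": 57.5, "Y": 57.9,
}
_PRE_PROLINE_CA_CORRECTION = -2.0


@dataclass
class PeakTable:
    """Per-residue NMR observables keyed by residue number.

    The underlying table has columns ``residue`` (int, 1-based, strictly
    increasing), ``aa`` (one-letter residue type), ``intensity`` (peak
    intensity, arbitrary units, >= 0) and optionally ``ca_shift`` (observed
    C-alpha chemical shift, ppm).  Prolines carry no backbone amide and must
    be absent.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).copy()
        required = {"residue", "aa", "intensity"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"peak table lacks columns {sorted(missing)}")
        df["residue"] = df["residue"].astype(int)
        df["intensity"] = df["intensity"].astype(float)
        if not df["residue"].is_monotonic_increasing or df["residue"].duplicated().any():
            raise ValueError("residue numbers must be strictly increasing")
        if (df["aa"] == "P").any():
            raise ValueError("prolines have no backbone amide and cannot appear in a peak table")
        if (df["intensity"] < 0).any():
            raise ValueError("peak intensities must be >= 0")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def residues(self) -> np.ndarray:
        return self.data["residue"].to_numpy()

    def intensity_series(self) -> pd.Series:
        return pd.Series(
            self.data["intensity"].to_numpy(), index=self.data["residue"], name="intensity"
        )

    def ca_series(self) -> pd.Series:
        if "ca_shift" not in self.data.columns:
            raise ValueError("peak table has no ca_shift column")
        return pd.Series(
            self.data["ca_shift"].to_numpy(), index=self.data["residue"], name="ca_shift"
        )

    @classmethod
    def from_tsv(cls, path) -> "PeakTable":
        """Read a tab-separated table with a header line.

        Raises a ValueError naming the offending line on malformed input.
        """
        try:
            df = pd.read_csv(path, sep="\t")
        except pd.errors.ParserError as err:
            raise ValueError(f"malformed TSV {path}: {err}") from err
        return cls(df)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


@dataclass
class RandomCoilModel:
    """Sequence-specific random-coil C-alpha shifts.

    ``baseline`` maps one-letter residue types to coil shifts (ppm);
    ``next_residue_corrections`` maps the identity of residue i+1 to an
    additive correction applied at residue i (the dominant sequence effect
    is the pre-proline shift).  ``provenance`` names the published table the
    values were taken from.
    """

    baseline: dict = field(default_factory=lambda: dict(_WISHART_CA))
    next_residue_corrections: dict = field(
        default_factory=lambda: {"P": _PRE_PROLINE_CA_CORRECTION}
    )
    provenance: str = (
        "Wishart et al. (1995) random-coil CA shifts, DSS-referenced, "
        "with a -2.0 ppm pre-proline correction"
    )

    def __post_init__(self) -> None:
        lacking = [aa for aa in AMINO_ACIDS if aa not in self.baseline]
        if lacking:
            raise ValueError(f"random-coil table lacks baseline entries for {lacking}")

    def predict(self, sequence: str, start_residue: int = 1) -> pd.Series:
        """Coil C-alpha shift for every residue of ``sequence``.

        The series is indexed by residue number; ``start_residue`` is the
        number of the first letter of ``sequence``.
        """
        shifts = {}
        for i, aa in enumerate(sequence):
            if aa not in self.baseline:
                raise ValueError(f"unknown residue type {aa!r} at position {start_residue + i}")
            value = self.baseline[aa]
            if i + 1 < len(sequence):
                value += self.next_residue_corrections.get(sequence[i + 1], 0.0)
            shifts[start_residue + i] = value
        return pd.Series(shifts, name="rc_ca_shift")

    @classmethod
    def from_csv(cls, path, provenance: str = "user-supplied table") -> "RandomCoilModel":
        """Load a replacement table: columns aa, ca_shift[, next_aa_correction].

        Rows with a non-empty ``next_aa`` column define neighbour
        corrections keyed by that residue type instead of baselines.
        """
        df = pd.read_csv(path)
        baseline = {}
        corrections = {}
        for _, row in df.iterrows():
            if "next_aa" in df.columns and isinstance(row.get("next_aa"), str) and row["next_aa"]:
                corrections[row["next_aa"]] = float(row["ca_shift"])
            else:
                baseline[str(row["aa"])] = float(row["ca_shift"])
        return cls(baseline=baseline, next_residue_corrections=corrections, provenance=provenance)


@dataclass(frozen=True)
class RegionCall:
    """One contiguous interacting region (inclusive residue interval)."""

    start_residue: int
    end_residue: int
    mean_ratio: float
    n_observed: int

    def __post_init__(self) -> None:
        if self.start_residue > self.end_residue:
            raise ValueError("region start must not exceed its end")


def intensity_ratio(bound: PeakTable, free: PeakTable) -> pd.Series:
    """Per-residue intensity ratio I/I0.

    I is the amide peak intensity with the binding partner added and I0 the
    intensity of the free protein.  Residues present in only one table get
    NaN.  A zero or negative free intensity at a shared residue is an error
    (the ratio would be undefined).
    """
    i_free = free.intensity_series()
    i_bound = bound.intensity_series()
    shared = i_free.index.intersection(i_bound.index)
    bad = shared[i_free.loc[shared] <= 0]
    if len(bad):
        raise ValueError(f"non-positive free intensity at residue(s) {list(bad)}")
    all_res = i_free.index.union(i_bound.index)
    ratio = (i_bound.reindex(all_res) / i_free.reindex(all_res)).astype(float)
    ratio.name = "intensity_ratio"
    return ratio


def secondary_shift(
    observed: PeakTable,
    sequence: str,
    rc: RandomCoilModel | None = None,
    start_residue: int = 1,
) -> pd.Series:
    """Secondary C-alpha shift ddCA = observed - random coil (ppm).

    ``sequence`` must cover the numbering of the observed residues and agree
    with the residue types recorded in the table.
    """
    rc = rc if rc is not None else RandomCoilModel()
    coil = rc.predict(sequence, start_residue=start_residue)
    obs = observed.ca_series()
    end = start_residue + len(sequence) - 1
    for res, aa in zip(observed.data["residue"], observed.data["aa"]):
        if res < start_residue or res > end:
            raise ValueError(f"residue {res} outside the sequence numbering [{start_residue}, {end}]")
        seq_aa = sequence[res - start_residue]
        if seq_aa != aa:
            raise ValueError(f"residue {res}: table says {aa!r} but sequence says {seq_aa!r}")
    delta = obs - coil.reindex(obs.index)
    delta.name = "delta_ca"
    return delta


def disorder_flag(profile: pd.Series, cutoff: float = 0.5) -> tuple[pd.Series, float]:
    """Flag residues as disordered where ``|ddCA| <= cutoff`` ppm.

    Returns the per-residue boolean flags and the flagged fraction over the
    observed (non-NaN) residues.  Values near zero of the chemical shift
    index indicate the absence of residual secondary structure.
    """
    profile = pd.Series(profile).dropna()
    if profile.empty:
        raise ValueError("empty chemical-shift-index profile")
    flags = profile.abs() <= cutoff
    return flags, float(flags.mean())


def call_interaction_region(
    profile: pd.Series,
    threshold: float = 0.5,
    min_run: int = 5,
    max_gap: int = 3,
) -> list[RegionCall]:
    """Call contiguous interacting regions from an I/I0 profile.

    A residue is attenuated when its observed ratio is below ``threshold``.
    Maximal runs of attenuated residues are built by bridging stretches of
    at most ``max_gap`` residues that are missing (proline, unassigned) or
    above threshold; runs with fewer than ``min_run`` observed attenuated
    residues are discarded.  Calls are returned sorted by start residue.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie strictly between 0 and 1")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    profile = pd.Series(profile)
    observed = profile.dropna()
    sub = observed[observed < threshold]
    if sub.empty:
        return []
    residues = np.asarray(sub.index, dtype=int)
    runs: list[tuple[int, int, int]] = []  # (start, end, n sub-threshold)
    run_start = residues[0]
    prev = residues[0]
    n_sub = 1
    for res in residues[1:]:
        if res - prev - 1 > max_gap:
            runs.append((run_start, prev, n_sub))
            run_start = res
            n_sub = 0
        prev = res
        n_sub += 1
    runs.append((run_start, prev, n_sub))
    return [_make_call(observed, s, e) for s, e, n in runs if n >= min_run]


def _make_call(observed: pd.Series, start: int, end: int) -> RegionCall:
    inside = observed.loc[(observed.index >= start) & (observed.index <= end)]
    return RegionCall(
        start_residue=int(start),
        end_residue=int(end),
        mean_ratio=float(inside.mean()),
        n_observed=int(len(inside)),
    )


def read_fasta(path) -> str:
    """Return the (single) protein sequence stored in a FASTA file."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record in {path}, found {len(records)}")
    return str(records[0].seq).upper()
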