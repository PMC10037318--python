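"""Residue binding scores and the position-9 helix-propensity classifier.

The binding score of residue *i* combines its surface contact fraction
``f_i`` with the adsorption free energy of the corresponding free amino acid
at the aqueous Au(111) interface:

    s_i = f_i * dG_ads(residue_i)      [kJ/mol]

The product convention is the default because it vanishes for residues that
never touch the surface and recovers the full adsorption free energy at
permanent contact, while keeping kJ/mol units.  The combining operator is
pluggable so alternatives can be swapped without touching callers.

Scores summed over a sequence range give cumulative binding scores; the score
of the ninth residue classifies the variant's expected nanoparticle-assembly
morphology, with the single-helix window at [-10, -1] kJ/mol (inclusive at
both ends).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from .contacts import ContactProfile
from .errors import ConfigurationError, InputError

__all__ = [
    "FreeEnergyTable",
    "BindingScoreReport",
    "residue_binding_scores",
    "cumulative_binding_score",
    "classify_position9",
    "default_free_energy_table",
    "SINGLE_HELIX_RANGE",
]

#: Position-9 score window (kJ/mol, inclusive) associated with single-helical
#: nanoparticle superstructures; below it binding is "strong" (double helix
#: territory), above it "weak/non-binding".
SINGLE_HELIX_RANGE = (-10.0, -1.0)

STRONG = "strong-binding"
SINGLE_HELIX = "single-helix-range"
WEAK = "weak/non-binding"


@dataclass
class FreeEnergyTable:
    """Adsorption free energies (kJ/mol) of amino acids at the aqueous Au(111) interface.

    Negative = favourable adsorption.  ``sources`` carries a provenance tag
    per entry ("representative", "user", "pmf", ...).
    """

    entries: dict[str, float]
    sources: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        bad = [k for k, v in self.entries.items() if not math.isfinite(v)]
        if bad:
            raise ConfigurationError(f"non-finite free energies for: {', '.join(bad)}")

    def __getitem__(self, residue_name: str) -> float:
        try:
            return self.entries[residue_name]
        except KeyError:
            raise ConfigurationError(
                f"no adsorption free energy for residue type {residue_name!r}"
            ) from None

    def __contains__(self, residue_name: str) -> bool:
        return residue_name in self.entries

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("residue_name\tdG_kJ_per_mol\tsource\n")
            for name, dg in self.entries.items():
                fh.write(f"{name}\t{dg}\t{self.sources.get(name, 'user')}\n")

    @classmethod
    def load(cls, path: str | os.PathLike) -> "FreeEnergyTable":
        """Read from TSV (residue_name, dG_kJ_per_mol[, source]) or YAML mapping."""
        path = str(path)
        if path.endswith((".yaml", ".yml")):
            with open(path) as fh:
                raw = yaml.safe_load(fh)
            rows = raw["residues"] if isinstance(raw, dict) and "residues" in raw else raw
            if isinstance(rows, dict):
                return cls(entries={k: float(v) for k, v in rows.items()})
            return cls(
                entries={r["residue_name"]: float(r["dG_kJ_per_mol"]) for r in rows},
                sources={r["residue_name"]: r.get("source", "user") for r in rows},
            )
        df = pd.read_csv(path, sep="\t", comment="#")
        if not {"residue_name", "dG_kJ_per_mol"}.issubset(df.columns):
            raise ConfigurationError(
                f"{path}: need columns residue_name, dG_kJ_per_mol"
            )
        sources = (
            dict(zip(df.residue_name, df.source)) if "source" in df.columns else {}
        )
        return cls(
            entries=dict(zip(df.residue_name.astype(str), df.dG_kJ_per_mol.astype(float))),
            sources=sources,
        )


def default_free_energy_table() -> FreeEnergyTable:
    """Representative per-residue adsorption free energies (kJ/mol) at aqueous Au(111).

    These are order-of-magnitude defaults chosen so the scoring machinery runs
    out of the box: sulfur-bearing and aromatic residues bind most strongly,
    small aliphatics weakly.  They are NOT measured values — replace them with
    a published or PMF-derived table (``FreeEnergyTable.load``) for any real
    analysis.  The modified residues (MOX = oxidised Met, CTB = tBu-protected
    Cys, COX = oxidised protected Cys) default to weak binding, reflecting a
    blocked/oxidised sulfur anchor; fill them from umbrella-sampling PMFs.
    """
    rep = {
        "ALA": -6.0, "ARG": -14.0, "ASN": -8.0, "ASP": -7.0, "CYS": -16.0,
        "GLN": -9.0, "GLU": -7.5, "GLY": -5.0, "HIS": -12.0, "ILE": -7.0,
        "LEU": -8.0, "LYS": -8.5, "MET": -13.0, "PHE": -15.0, "PRO": -6.5,
        "SER": -8.0, "THR": -9.0, "TRP": -18.0, "TYR": -17.0, "VAL": -6.5,
        "MOX": -4.0, "CTB": -3.0, "COX": -2.0,
    }
    return FreeEnergyTable(entries=rep, sources={k: "representative" for k in rep})


def _product(f: float, dg: float) -> float:
    return f * dg


@dataclass
class BindingScoreReport:
    """Per-residue scores plus cumulative range sums and the position-9 call."""

    residue_names: list[str]
    positions: list[int]
    contact_fractions: np.ndarray
    residue_scores: np.ndarray  # kJ/mol
    cumulative: dict[str, float]
    position9_score: float | None
    position9_class: str | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "residue_name": self.residue_names,
                "contact_fraction": self.contact_fractions,
                "binding_score_kJ_per_mol": self.residue_scores,
            }
        )

    def to_tsv(self, path: str | os.PathLike, header_lines: list[str] | None = None):
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            for name, value in self.cumulative.items():
                fh.write(f"# cumulative {name} = {value:.6g} kJ/mol\n")
            if self.position9_score is not None:
                fh.write(
                    f"# position9 score = {self.position9_score:.6g} kJ/mol "
                    f"({self.position9_class})\n"
                )
            self.to_frame().to_csv(fh, sep="\t", index=False)

    def to_json(self, path: str | os.PathLike | None = None) -> str:
        payload = {
            "residues": [
                {
                    "position": int(p),
                    "residue_name": n,
                    "contact_fraction": float(f),
                    "binding_score_kJ_per_mol": float(s),
                }
                for p, n, f, s in zip(
                    self.positions,
                    self.residue_names,
                    self.contact_fractions,
                    self.residue_scores,
                )
            ],
            "cumulative_kJ_per_mol": {k: float(v) for k, v in self.cumulative.items()},
            "position9_score_kJ_per_mol": self.position9_score,
            "position9_class": self.position9_class,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def classify_position9(score9: float) -> str:
    """Helix-propensity label from the ninth-residue binding score (kJ/mol)."""
    if not math.isfinite(score9):
        raise InputError(f"position-9 score must be finite, got {score9}")
    lo, hi = SINGLE_HELIX_RANGE
    if score9 < lo:
        return STRONG
    if score9 <= hi:
        return SINGLE_HELIX
    return WEAK


def residue_binding_scores(
    profile: ContactProfile,
    table: FreeEnergyTable | None = None,
    combine: Callable[[float, float], float] = _product,
    n_half: tuple[int, int] = (1, 6),
    c_half: tuple[int, int] = (7, 12),
) -> BindingScoreReport:
    """Per-residue binding scores s_i = combine(f_i, dG_i) plus range sums.

    Default ranges follow the dodecapeptide layout: N-terminal half residues
    1-6, C-terminal (particle-binding) half 7-12; ranges are clipped to the
    actual sequence.
    """
    if table is None:
        table = default_free_energy_table()
    missing = sorted(set(profile.residue_names) - set(table.entries))
    if missing:
        raise ConfigurationError(
            "free-energy table is missing entries for: " + ", ".join(missing)
        )
    scores = np.array(
        [
            combine(float(f), table[name])
            for f, name in zip(profile.fractions, profile.residue_names)
        ]
    )
    scores += 0.0  # normalise -0.0 from zero-contact residues
    report = BindingScoreReport(
        residue_names=list(profile.residue_names),
        positions=list(profile.positions),
        contact_fractions=np.asarray(profile.fractions, dtype=float),
        residue_scores=scores,
        cumulative={},
        position9_score=None,
        position9_class=None,
    )
    for label, (lo, hi) in (
        (f"N-half ({n_half[0]}-{n_half[1]})", n_half),
        (f"C-half ({c_half[0]}-{c_half[1]})", c_half),
    ):
        # sum over the positions actually present in the (possibly partial)
        # sequence; the strict public op still rejects absent positions
        members = [
            s for p, s in zip(report.positions, scores) if lo <= p <= hi
        ]
        if members:
            report.cumulative[label] = float(sum(members))
    if 9 in profile.positions:
        s9 = float(scores[profile.positions.index(9)])
        report.position9_score = s9
        report.position9_class = classify_position9(s9)
    return report


def cumulative_binding_score(
    report: BindingScoreReport, residue_range: tuple[int, int]
) -> float:
    """Sum of residue scores over an inclusive 1-based position interval.

    An empty interval (lo > hi) sums to 0; positions outside the sequence are
    an error.
    """
    lo, hi = residue_range
    if lo > hi:
        return 0.0
    present = set(report.positions)
    out = [p for p in range(lo, hi + 1) if p not in present]
    if out:
        raise InputError(
            f"range {lo}-{hi} includes positions absent from the sequence: {out}"
        )
    return float(
        sum(
            s
            for p, s in zip(report.positions, report.residue_scores)
            if lo <= p <= hi
        )
    )
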