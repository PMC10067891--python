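"""Nearest-neighbor melting temperatures and the Tm-variance statistic.

The melting temperature Tm is the temperature at which half the DNA
duplexes in solution dissociate.  It is computed from nearest-neighbor
(NN) stacking thermodynamics — duplex dH/dS as a sum over adjacent base
pairs with initiation and terminal corrections — with a primer
concentration term and a monovalent-salt correction, delegated to
Biopython's ``MeltingTemp`` implementation.

Codeword sets whose members share similar Tm values anneal uniformly in
PCR, so the *variance* of per-word Tm across a code set measures its
thermodynamic homogeneity: the smaller the variance, the more uniform
(and less cross-hybridisation-prone) the set.  :func:`compare_regimes`
tabulates this statistic across constraint regimes.

Defaults: 200 nM primer, 50 mM monovalent Na+ (a typical PCR buffer;
a nanomolar salt level would be physically implausible), SantaLucia
unified NN parameters with the entropy-based salt correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from Bio.SeqUtils import MeltingTemp as _mt

from .codeset import CodeSet
from .dna_core import DnaSequence

__all__ = ["NN_TABLES", "ThermoParams", "melting_temperature", "tm_variance",
           "tm_table", "compare_regimes"]

NN_TABLES = {
    "santalucia_unified": _mt.DNA_NN3,  # Allawi & SantaLucia unified set
    "breslauer": _mt.DNA_NN1,
    "sugimoto": _mt.DNA_NN2,
    "santalucia_2004": _mt.DNA_NN4,
}


@dataclass(frozen=True)
class ThermoParams:
    """Hybridisation conditions for the NN Tm model.

    ``primer_nM``: total single-strand concentration in nanomolar;
    ``salt_mM``: monovalent cation concentration in millimolar;
    ``nn_table``: key into :data:`NN_TABLES`;
    ``salt_correction``: Biopython salt-correction method id (5 =
    entropy-based correction of the unified parameter set).
    """

    primer_nM: float = 200.0
    salt_mM: float = 50.0
    nn_table: str = "santalucia_unified"
    salt_correction: int = 5

    def __post_init__(self) -> None:
        if self.primer_nM <= 0 or self.salt_mM <= 0:
            raise ValueError("concentrations must be positive")
        if self.nn_table not in NN_TABLES:
            raise ValueError(
                f"unknown NN table {self.nn_table!r}; "
                f"choose from {sorted(NN_TABLES)}"
            )


def melting_temperature(x: str, p: ThermoParams | None = None) -> float:
    """Nearest-neighbor Tm of ``x`` in degrees Celsius."""
    p = p or ThermoParams()
    x = DnaSequence(x)
    if len(x) < 2:
        raise ValueError("Tm needs at least 2 bases (one NN stack)")
    return float(
        _mt.Tm_NN(
            str(x),
            nn_table=NN_TABLES[p.nn_table],
            dnac1=p.primer_nM,
            dnac2=0,
            Na=p.salt_mM,
            saltcorr=p.salt_correction,
        )
    )


def tm_variance(cs: CodeSet | Iterable[str], p: ThermoParams | None = None) -> float:
    """Population variance (degC^2) of per-word Tm over a code set."""
    words = list(cs)
    if len(words) < 2:
        raise ValueError("Tm variance needs at least 2 codewords")
    tms = [melting_temperature(w, p) for w in words]
    return float(np.var(tms))


def tm_table(cs: CodeSet | Iterable[str], p: ThermoParams | None = None) -> pd.DataFrame:
    """Per-word Tm values of a code set."""
    p = p or ThermoParams()
    return pd.DataFrame(
        [{"word": str(w), "tm_C": melting_temperature(w, p)} for w in cs]
    )


def compare_regimes(
    code_sets: dict[str, CodeSet], p: ThermoParams | None = None
) -> pd.DataFrame:
    """Tm summary (mean, variance) per labelled constraint regime."""
    p = p or ThermoParams()
    rows = []
    for label, cs in code_sets.items():
        tms = [melting_temperature(w, p) for w in cs]
        rows.append(
            {
                "regime": label,
                "K": len(tms),
                "n": cs.n,
                "tm_mean_C": float(np.mean(tms)),
                "tm_variance_C2": float(np.var(tms)),
            }
        )
    return pd.DataFrame(rows)
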