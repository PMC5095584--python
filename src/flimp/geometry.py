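"""Linear chain model of ligand-bound receptor oligomers.

Ligand-bound extracellular back-to-back dimers stack into chains through a
face-to-face interface that engages all ligand-binding sites except the two
at the open ends, so an oligomer of any order binds at most two ligands.
The pairwise ligand separation therefore grows linearly with the number of
stacked dimers: a tetramer (two dimers) anchors the series at 18.5 nm and
each additional dimer adds ~7.5 nm, giving 26 nm for a hexamer, 33.5 nm for
an octamer and 41 nm for a decamer.  Dye plus linker dimensions add a fixed
1.1 nm to the ligand-ligand distance, so the fluorophore-to-fluorophore
tetramer separation expected in a measurement is 19.6 nm.

The lone dimer is not part of the chain series: its dye-dye separation
(12.5 +/- 0.3 nm) comes from an independent accessible-volume computation on
the crystallographic dimer and is stored here as a separate constant.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "OligomerChainModel",
    "SpeciesInterval",
    "DIMER_DYE_SEPARATION_NM",
    "DIMER_DYE_TOLERANCE_NM",
    "expected_interval",
]

# Dye-dye distance for the two ligands of a back-to-back dimer, from the
# accessible-volume model of the dye/linker on the crystallographic dimer.
# Independent of the chain model.
DIMER_DYE_SEPARATION_NM: float = 12.5
DIMER_DYE_TOLERANCE_NM: float = 0.3

# Tetramer dye-dye interval half-width (19.6 +/- 0.5 nm).
_TETRAMER_DYE_SEPARATION_NM: float = 19.6
_TETRAMER_DYE_TOLERANCE_NM: float = 0.5


@dataclass(frozen=True)
class OligomerChainModel:
    """Linear model for pairwise ligand separations in stacked-dimer chains.

    Parameters
    ----------
    tetramer_anchor_nm : float
        Ligand-ligand separation of the tetramer (two stacked dimers).
    per_dimer_increment_nm : float
        Separation added per extra stacked dimer.
    dye_contribution_nm : float
        Fixed dye/linker contribution converting a ligand-ligand distance
        into the fluorophore-fluorophore distance a measurement reports.
    """

    tetramer_anchor_nm: float = 18.5
    per_dimer_increment_nm: float = 7.5
    dye_contribution_nm: float = 1.1

    def __post_init__(self) -> None:
        if self.tetramer_anchor_nm <= 0:
            raise ValueError("tetramer_anchor_nm must be positive")
        if self.per_dimer_increment_nm <= 0:
            raise ValueError("per_dimer_increment_nm must be positive")
        if self.dye_contribution_nm < 0:
            raise ValueError("dye_contribution_nm must be non-negative")

    def predict_ligand_separation(self, n_dimers: int) -> float:
        """Ligand-ligand separation (nm) of a chain of ``n_dimers`` dimers.

        The chain starts at the tetramer (``n_dimers=2``); a lone dimer's
        two-ligand separation is an independent constant, not a chain
        prediction.
        """
        if int(n_dimers) != n_dimers:
            raise ValueError("n_dimers must be an integer")
        if n_dimers < 2:
            raise ValueError(
                "chain model applies from the tetramer (n_dimers=2) upward"
            )
        return self.tetramer_anchor_nm + (n_dimers - 2) * self.per_dimer_increment_nm

    def dye_corrected_separation(self, ligand_separation_nm: float) -> float:
        """Fluorophore-fluorophore distance for a given ligand separation."""
        if ligand_separation_nm < 0:
            raise ValueError("ligand separation must be non-negative")
        return ligand_separation_nm + self.dye_contribution_nm

    def predict_dye_separation(self, n_dimers: int) -> float:
        """Dye-corrected separation for an oligomer of ``n_dimers`` dimers."""
        return self.dye_corrected_separation(self.predict_ligand_separation(n_dimers))

    def prediction_table(self, n_max: int = 5) -> list[tuple[int, float, float]]:
        """Rows of (n_dimers, ligand separation, dye-corrected separation)."""
        return [
            (n, self.predict_ligand_separation(n), self.predict_dye_separation(n))
            for n in range(2, n_max + 1)
        ]


@dataclass(frozen=True)
class SpeciesInterval:
    """A labelled interval of expected dye-dye separations (nm)."""

    label: str
    low_nm: float
    high_nm: float

    def __post_init__(self) -> None:
        if self.low_nm < 0:
            raise ValueError("low_nm must be non-negative")
        if not self.low_nm < self.high_nm:
            raise ValueError("interval must satisfy low_nm < high_nm")

    def intersects(self, low: float, high: float) -> bool:
        """Nonempty intersection with the closed interval [low, high]."""
        return low <= self.high_nm and self.low_nm <= high


def expected_interval(label: str) -> SpeciesInterval:
    """Expected separation interval for a named species.

    ``dimer`` is the accessible-volume dimer constant 12.5 +/- 0.3 nm;
    ``tetramer`` the dye-corrected chain tetramer 19.6 +/- 0.5 nm; ``region``
    the dimer-tetramer region 0-20.1 nm used as the denominator when
    estimating species fractions.
    """
    if label == "dimer":
        return SpeciesInterval(
            "dimer",
            DIMER_DYE_SEPARATION_NM - DIMER_DYE_TOLERANCE_NM,
            DIMER_DYE_SEPARATION_NM + DIMER_DYE_TOLERANCE_NM,
        )
    if label == "tetramer":
        return SpeciesInterval(
            "tetramer",
            _TETRAMER_DYE_SEPARATION_NM - _TETRAMER_DYE_TOLERANCE_NM,
            _TETRAMER_DYE_SEPARATION_NM + _TETRAMER_DYE_TOLERANCE_NM,
        )
    if label == "region":
        return SpeciesInterval(
            "region",
            0.0,
            _TETRAMER_DYE_SEPARATION_NM + _TETRAMER_DYE_TOLERANCE_NM,
        )
    raise KeyError(f"unknown species label: {label!r}")
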