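"""Core data model: markers and the diploid genotype matrix.

Genotypes are stored as alt-allele dosage codes in an ``int8`` matrix with one
row per individual and one column per marker; ``MISSING`` (-1) marks a failed
call.  Markers are kept sorted by (chromosome, position) at all times so that
windowed pair enumeration can rely on position order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

MISSING: int = -1

#: Chromosome labels accepted besides the autosome integers 1-29.  They are
#: parsed (so files containing them load) but dropped by the autosome filter.
_SPECIAL_CHROMS = {"X": 30, "Y": 31, "XY": 32, "MT": 33, "M": 33}
_AUTOSOME_MAX = 29


def parse_chromosome(token: str) -> int:
    """Map a PLINK chromosome token to an integer label.

    Autosomes stay as their integer; X/Y/XY/MT get codes above 29 so the
    autosome filter can recognise them.
    """
    tok = str(token).strip().upper()
    if tok in _SPECIAL_CHROMS:
        return _SPECIAL_CHROMS[tok]
    try:
        return int(tok)
    except ValueError as exc:
        raise ValueError(f"unparseable chromosome label: {token!r}") from exc


def is_autosome(chrom: int) -> bool:
    return 1 <= chrom <= _AUTOSOME_MAX


@dataclass(frozen=True)
class Marker:
    """One biallelic SNP: identifier, map position and the two alleles.

    ``allele_a`` is the allele whose dosage is *not* counted (PLINK A2/major by
    file order), ``allele_b`` the counted one.  ``position_bp`` is 1-based.
    """

    id: str
    chromosome: int
    position_bp: int
    allele_a: str = "A"
    allele_b: str = "B"

    def __post_init__(self) -> None:
        if self.position_bp < 0:
            raise ValueError(f"negative position for {self.id}")


@dataclass
class GenotypeDataset:
    """Marker map + individual roster + dosage matrix.

    Invariants: ``genotypes.shape == (len(individuals), len(markers))``,
    markers sorted by (chromosome, position_bp), dosages in {0, 1, 2, MISSING}.
    """

    markers: list[Marker]
    individuals: list[str]
    genotypes: np.ndarray  # int8, (n_individuals, n_markers)
    #: which allele the dosage counts, recorded so MAF is orientation-free
    counted_allele: str = "B"
    _marker_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotype matrix must be 2-D")
        n, m = self.genotypes.shape
        if n != len(self.individuals) or m != len(self.markers):
            raise ValueError(
                f"genotype matrix {self.genotypes.shape} inconsistent with "
                f"{len(self.individuals)} individuals x {len(self.markers)} markers"
            )
        valid = np.isin(self.genotypes, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.genotypes[~valid])
            raise ValueError(f"invalid dosage codes {bad.tolist()}")
        self._ensure_sorted()
        self._rebuild_index()

    # -- construction helpers -------------------------------------------------

    def _ensure_sorted(self) -> None:
        keys = [(m.chromosome, m.position_bp) for m in self.markers]
        if keys != sorted(keys):
            order = np.array(
                sorted(range(len(keys)), key=keys.__getitem__), dtype=np.intp
            )
            self.markers = [self.markers[i] for i in order]
            self.genotypes = np.ascontiguousarray(self.genotypes[:, order])

    def _rebuild_index(self) -> None:
        self._marker_index = {m.id: i for i, m in enumerate(self.markers)}
        if len(self._marker_index) != len(self.markers):
            seen: set[str] = set()
            dup = [m.id for m in self.markers if m.id in seen or seen.add(m.id)]
            raise ValueError(f"duplicate marker ids: {sorted(set(dup))[:5]}")

    # -- basic accessors ------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def chromosomes(self) -> list[int]:
        return sorted({m.chromosome for m in self.markers})

    def positions(self) -> np.ndarray:
        return np.array([m.position_bp for m in self.markers], dtype=np.int64)

    def chromosome_codes(self) -> np.ndarray:
        return np.array([m.chromosome for m in self.markers], dtype=np.int32)

    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    # -- subsetting -----------------------------------------------------------

    def subset(
        self,
        individual_ids: Sequence[str] | None = None,
        marker_ids: Sequence[str] | None = None,
    ) -> "GenotypeDataset":
        """Order-preserving subset by individual and/or marker identifier.

        Unknown identifiers raise a ``KeyError`` listing every offender.
        """
        if individual_ids is None:
            rows = np.arange(self.n_individuals)
            inds = list(self.individuals)
        else:
            lookup = {iid: i for i, iid in enumerate(self.individuals)}
            missing = [i for i in individual_ids if i not in lookup]
            if missing:
                raise KeyError(f"unknown individual ids: {missing}")
            rows = np.array([lookup[i] for i in individual_ids], dtype=np.intp)
            inds = list(individual_ids)
        if marker_ids is None:
            cols = np.arange(self.n_markers)
            marks = list(self.markers)
        else:
            missing = [m for m in marker_ids if m not in self._marker_index]
            if missing:
                raise KeyError(f"unknown marker ids: {missing}")
            cols = np.array(
                [self._marker_index[m] for m in marker_ids], dtype=np.intp
            )
            marks = [self.markers[c] for c in cols]
        geno = self.genotypes[np.ix_(rows, cols)]
        return GenotypeDataset(marks, inds, geno, counted_allele=self.counted_allele)

    def take_individuals(self, rows: np.ndarray) -> "GenotypeDataset":
        """Positional row subset (used by the sample-size sensitivity analysis)."""
        inds = [self.individuals[int(r)] for r in rows]
        return GenotypeDataset(
            list(self.markers),
            inds,
            self.genotypes[np.asarray(rows, dtype=np.intp), :],
            counted_allele=self.counted_allele,
        )

    def take_markers(self, cols: np.ndarray) -> "GenotypeDataset":
        cols = np.asarray(cols, dtype=np.intp)
        return GenotypeDataset(
            [self.markers[int(c)] for c in cols],
            list(self.individuals),
            self.genotypes[:, cols],
            counted_allele=self.counted_allele,
        )

    def flip_counted_allele(self) -> "GenotypeDataset":
        """Return the dataset with dosages counting the other allele (2 - g)."""
        g = self.genotypes.copy()
        obs = g != MISSING
        g[obs] = 2 - g[obs]
        marks = [
            replace(m, allele_a=m.allele_b, allele_b=m.allele_a)
            for m in self.markers
        ]
        new_label = "A" if self.counted_allele == "B" else "B"
        return GenotypeDataset(marks, list(self.individuals), g, counted_allele=new_label)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.markers == other.markers
            and self.individuals == other.individuals
            and np.array_equal(self.genotypes, other.genotypes)
        )


def harmonize_alleles(dataset: GenotypeDataset, reference: GenotypeDataset) -> GenotypeDataset:
    """Flip per-marker allele orientation in ``dataset`` to match ``reference``.

    PED text files do not record which allele is counted, so a re-read dataset
    may have individual columns coded on the opposite allele.  Columns whose
    (allele_a, allele_b) pair is swapped relative to ``reference`` get their
    dosages flipped (g -> 2 - g); inconsistent allele pairs raise.
    """
    if [m.id for m in dataset.markers] != [m.id for m in reference.markers]:
        raise ValueError("marker rosters differ; cannot harmonize")
    geno = dataset.genotypes.copy()
    markers = list(dataset.markers)
    for j, (mk, ref) in enumerate(zip(dataset.markers, reference.markers)):
        if (mk.allele_a, mk.allele_b) == (ref.allele_a, ref.allele_b):
            continue
        if (mk.allele_a, mk.allele_b) == (ref.allele_b, ref.allele_a):
            col = geno[:, j]
            obs = col != MISSING
            col[obs] = 2 - col[obs]
            markers[j] = ref
        else:
            # monomorphic-in-file columns only ever saw one allele; trust ref
            seen = {mk.allele_a, mk.allele_b} - {"A", "B"}
            if seen <= {ref.allele_a, ref.allele_b}:
                if seen == {ref.allele_b}:
                    # everyone hom for ref's counted allele: re-read coded it 0
                    col = geno[:, j]
                    obs = col != MISSING
                    col[obs] = 2 - col[obs]
                markers[j] = ref
        if {markers[j].allele_a, markers[j].allele_b} != {ref.allele_a, ref.allele_b}:
            raise ValueError(f"alleles at {mk.id} incompatible with reference")
    return GenotypeDataset(
        markers, list(dataset.individuals), geno, counted_allele=reference.counted_allele
    )
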