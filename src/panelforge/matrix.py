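"""Genotype matrix container: individuals x loci dosage codes with population labels.

Dosage coding follows the 0 / 0.5 / 1 convention for minor-allele homozygote,
heterozygote and major-allele homozygote respectively; missing calls are NaN.
This container is the common currency of the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The three legal non-missing dosage codes.
DOSAGE_CODES = (0.0, 0.5, 1.0)

MISSING = np.nan


def _as_str_array(x) -> np.ndarray:
    return np.asarray(list(x), dtype=object)


@dataclass
class GenotypeMatrix:
    """Diploid bi-allelic genotypes as dosage codes.

    Parameters
    ----------
    individual_ids : sequence of str
        Unique identifier per individual (rows).
    populations : sequence of str
        Population label per individual (e.g. sampling river); non-empty.
    locus_ids : sequence of str
        Unique locus identifier per column.
    dosages : ndarray of shape (n_individuals, n_loci)
        Values in {0, 0.5, 1} or NaN for missing.
    """

    individual_ids: np.ndarray
    populations: np.ndarray
    locus_ids: np.ndarray
    dosages: np.ndarray
    _locus_index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        self.individual_ids = _as_str_array(self.individual_ids)
        self.populations = _as_str_array(self.populations)
        self.locus_ids = _as_str_array(self.locus_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x loci)")
        n, p = self.dosages.shape
        if len(self.individual_ids) != n:
            raise ValueError(
                f"{len(self.individual_ids)} individual ids for {n} rows"
            )
        if len(self.populations) != n:
            raise ValueError(f"{len(self.populations)} population labels for {n} rows")
        if len(self.locus_ids) != p:
            raise ValueError(f"{len(self.locus_ids)} locus ids for {p} columns")
        if len(set(self.locus_ids)) != p:
            raise ValueError("locus ids must be unique")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids must be unique")
        if any(lbl == "" for lbl in self.populations):
            raise ValueError("every individual needs a non-empty population label")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, DOSAGE_CODES).all():
            bad = vals[~np.isin(vals, DOSAGE_CODES)][0]
            raise ValueError(f"non-missing dosage {bad!r} outside {{0, 0.5, 1}}")
        self._locus_index = {l: j for j, l in enumerate(self.locus_ids)}

    # ------------------------------------------------------------------ views
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def population_names(self) -> list[str]:
        """Distinct population labels, sorted for determinism."""
        return sorted(set(self.populations))

    def locus_indices(self, locus_ids) -> np.ndarray:
        idx = []
        for l in locus_ids:
            try:
                idx.append(self._locus_index[l])
            except KeyError:
                raise KeyError(f"unknown locus id {l!r}") from None
        return np.asarray(idx, dtype=int)

    # ------------------------------------------------------------- subsetting
    def subset_loci(self, whitelist) -> "GenotypeMatrix":
        """Restrict to the given loci, columns ordered as the whitelist."""
        whitelist = list(whitelist)
        if len(set(whitelist)) != len(whitelist):
            raise ValueError("whitelist contains duplicate locus ids")
        j = self.locus_indices(whitelist)
        return GenotypeMatrix(
            self.individual_ids,
            self.populations,
            whitelist,
            self.dosages[:, j] if len(j) else np.empty((self.n_individuals, 0)),
        )

    def subset_individuals(self, mask_or_ids) -> "GenotypeMatrix":
        m = np.asarray(mask_or_ids)
        if m.dtype == bool:
            sel = m
        else:
            wanted = set(m.tolist())
            sel = np.array([i in wanted for i in self.individual_ids])
        return GenotypeMatrix(
            self.individual_ids[sel],
            self.populations[sel],
            self.locus_ids,
            self.dosages[sel],
        )

    # ------------------------------------------------------------ conversion
    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.dosages, index=list(self.individual_ids), columns=list(self.locus_ids)
        )
        df.insert(0, "population", list(self.populations))
        df.index.name = "individual"
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        if "population" not in df.columns:
            raise ValueError("dataframe needs a 'population' column")
        loci = [c for c in df.columns if c != "population"]
        return cls(
            df.index.astype(str),
            df["population"].astype(str),
            loci,
            df[loci].to_numpy(dtype=float),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.individual_ids.copy(),
            self.populations.copy(),
            self.locus_ids.copy(),
            self.dosages.copy(),
        )

    # ----------------------------------------------------------------- stats
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def pop_indices(self) -> dict[str, np.ndarray]:
        """Row indices per population label."""
        return {
            p: np.flatnonzero(self.populations == p) for p in self.population_names
        }

    def minor_allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-locus (minor allele count, total called alleles) pooled over all
        individuals.  Dosage d carries ``2*(1-d)`` minor alleles."""
        called = ~np.isnan(self.dosages)
        minor = np.where(called, 2.0 * (1.0 - self.dosages), 0.0).sum(axis=0)
        total = 2.0 * called.sum(axis=0)
        return minor, total
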