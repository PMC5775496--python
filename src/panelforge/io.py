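"""Reading and writing genotype data.

Two interchange formats are supported:

* **Genepop** — the population-genetics exchange format: a title line, locus
  names (one per line or comma-separated), then ``POP``-delimited blocks of
  ``individual_id ,  0101 0202 ...`` rows with 2- or 3-digit allele codes
  (``00``/``000`` = missing allele).  Population labels follow the common
  ``POPNAME_SAMPLEID`` convention: the label is the token before the first
  underscore in an individual's id; blocks without that convention get
  ``pop1``, ``pop2``, ...
* **TSV matrix** — a plain table with columns ``individual``, ``population``
  and one column per locus holding dosage codes (``NA`` = missing).

Diploid calls are encoded as dosages 0 / 0.5 / 1 for minor homozygote,
heterozygote and major homozygote.  The minor allele is defined globally,
across all populations pooled; frequency ties at 0.5 break to the
lexicographically smaller allele code.
"""

from __future__ import annotations

import logging
import re
from collections import Counter

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


class GenepopParseError(ValueError):
    pass


class PloidyError(ValueError):
    pass


class EncodingError(ValueError):
    pass


# --------------------------------------------------------------------- dosage
def encode_dosage(call, minor_allele, major_allele=None) -> float:
    """Encode an unordered diploid allele pair as a dosage code.

    minor/minor -> 0, heterozygote -> 0.5, major/major -> 1; a call with any
    unknown allele (``None``) is missing.  If *major_allele* is given, alleles
    outside {minor, major} raise :class:`EncodingError`.
    """
    a, b = call
    if a is None or b is None:
        return MISSING
    for x in (a, b):
        if major_allele is not None and x not in (minor_allele, major_allele):
            raise EncodingError(
                f"allele {x!r} is neither minor ({minor_allele!r}) nor "
                f"major ({major_allele!r})"
            )
    n_minor = (a == minor_allele) + (b == minor_allele)
    return 1.0 - n_minor / 2.0


def global_minor_allele(allele_counts: Counter):
    """Pick the globally rarer allele; ties break lexicographically."""
    alleles = sorted(allele_counts)  # lexicographic, deterministic
    if len(alleles) == 1:
        return None, alleles[0]  # monomorphic: only a major allele
    (a, b) = alleles
    if allele_counts[a] < allele_counts[b]:
        return a, b
    if allele_counts[b] < allele_counts[a]:
        return b, a
    return a, b  # tie at 0.5: lexicographically smaller is minor


# -------------------------------------------------------------------- genepop
def _parse_genepop_lines(lines):
    """Split raw lines into (locus names, list of POP blocks of rows)."""
    if not lines:
        raise GenepopParseError("empty Genepop file")
    body = lines[1:]  # line 1 is the title, ignored
    is_pop = [bool(re.fullmatch(r"pop", l.strip(), re.IGNORECASE)) for l in body]
    if not any(is_pop):
        raise GenepopParseError("no POP line found (line 2 onward)")
    first_pop = is_pop.index(True)
    locus_lines = [l.strip() for l in body[:first_pop] if l.strip()]
    loci = []
    for l in locus_lines:
        loci.extend(t.strip() for t in l.split(",") if t.strip())
    if not loci:
        raise GenepopParseError("no locus names before the first POP line")

    blocks, current = [], None
    for off, (line, pop_marker) in enumerate(zip(body, is_pop)):
        lineno = off + 2
        if pop_marker:
            current = []
            blocks.append(current)
        elif off > first_pop and line.strip():
            if current is None:  # pragma: no cover - guarded by first_pop
                raise GenepopParseError(f"line {lineno}: data row before any POP")
            current.append((lineno, line))
    for k, b in enumerate(blocks):
        if not b:
            raise GenepopParseError(f"POP block {k + 1} contains no individuals")
    return loci, blocks


def _split_genotype_row(lineno, line, n_loci):
    if "," not in line:
        raise GenepopParseError(f"line {lineno}: no comma separating id from genotypes")
    ind, rest = line.split(",", 1)
    geno = rest.split()
    if len(geno) != n_loci:
        raise GenepopParseError(
            f"line {lineno}: {len(geno)} genotypes for {n_loci} loci"
        )
    return ind.strip(), geno


def read_genepop(path) -> GenotypeMatrix:
    """Read a Genepop file into a :class:`GenotypeMatrix`.

    Allele width (2 vs 3 digits) is auto-detected per file; mixed widths are
    rejected.  Alleles at each locus are mapped to minor/major by pooled
    global frequency and encoded per :func:`encode_dosage`; an allele code of
    all zeros is a missing allele.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    loci, blocks = _parse_genepop_lines(lines)

    rows = []  # (lineno, ind_id, [genotype strings])
    for block in blocks:
        parsed = [_split_genotype_row(ln, line, len(loci)) for ln, line in block]
        rows.append(parsed)

    widths = {len(g) for block in rows for _, gts in block for g in gts}
    if not widths <= {4, 6}:
        bad = sorted(widths - {4, 6})
        raise GenepopParseError(f"genotype token lengths {bad}: expected 4 or 6 digits")
    if len(widths) > 1:
        raise GenepopParseError("mixed 2- and 3-digit allele codes in one file")
    w = widths.pop() // 2
    zero = "0" * w

    def alleles_of(g):
        a, b = g[:w], g[w:]
        return (None if a == zero else a, None if b == zero else b)

    # pooled allele counts per locus -> global minor allele
    n_loci = len(loci)
    counts = [Counter() for _ in range(n_loci)]
    for block in rows:
        for _, gts in block:
            for j, g in enumerate(gts):
                for al in alleles_of(g):
                    if al is not None:
                        counts[j][al] += 1
    minor_major = []
    for locus, c in zip(loci, counts):
        if len(c) > 2:
            raise PloidyError(f"locus {locus!r} has {len(c)} alleles: {sorted(c)}")
        minor_major.append(global_minor_allele(c) if c else (None, None))

    ind_ids, pops, dosage_rows = [], [], []
    seen = Counter()
    for k, block in enumerate(rows):
        first = block[0][0]
        label = first.split("_", 1)[0] if "_" in first else f"pop{k + 1}"
        for ind, gts in block:
            seen[ind] += 1
            if seen[ind] > 1:
                new = f"{ind}.{seen[ind]}"
                log.warning("duplicate individual id %r renamed to %r", ind, new)
                ind = new
            ind_ids.append(ind)
            pops.append(label)
            row = np.empty(n_loci)
            for j, g in enumerate(gts):
                pair = alleles_of(g)
                minor, major = minor_major[j]
                if major is None:  # locus never called
                    row[j] = MISSING
                else:
                    row[j] = encode_dosage(pair, minor)
            dosage_rows.append(row)

    return GenotypeMatrix(ind_ids, pops, loci, np.vstack(dosage_rows))


def write_genepop(m: GenotypeMatrix, path, title="panelforge export") -> None:
    """Write a matrix as Genepop with 2-digit allele codes (01=minor, 02=major).

    Individual ids are prefixed with ``<population>_`` where not already so,
    which is how the population label survives a round-trip.
    """
    code = {0.0: "0101", 0.5: "0102", 1.0: "0202"}
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for l in m.locus_ids:
            fh.write(str(l) + "\n")
        for pop in m.population_names:
            fh.write("POP\n")
            for i in np.flatnonzero(m.populations == pop):
                ind = m.individual_ids[i]
                if not str(ind).startswith(f"{pop}_"):
                    ind = f"{pop}_{ind}"
                gts = " ".join(
                    "0000" if np.isnan(d) else code[d] for d in m.dosages[i]
                )
                fh.write(f"{ind} ,  {gts}\n")


# ------------------------------------------------------------------------ TSV
def read_matrix_tsv(path) -> GenotypeMatrix:
    """Read the TSV matrix format (individual, population, one column per locus)."""
    df = pd.read_csv(path, sep="\t", dtype={"individual": str, "population": str},
                     na_values=["NA"], keep_default_na=False)
    if df.columns[0] != "individual" or df.columns[1] != "population":
        raise ValueError("TSV matrix must start with 'individual' and 'population' columns")
    loci = list(df.columns[2:])
    return GenotypeMatrix(
        df["individual"], df["population"], loci, df[loci].to_numpy(dtype=float)
    )


def write_matrix_tsv(m: GenotypeMatrix, path) -> None:
    df = m.to_dataframe().reset_index()
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ------------------------------------------------------------------ whitelist
def read_whitelist(path) -> list[str]:
    """Plain-text whitelist: one locus id per line, blanks ignored."""
    with open(path) as fh:
        return [l.strip() for l in fh if l.strip()]


def write_whitelist(locus_ids, path) -> None:
    with open(path, "w") as fh:
        for l in locus_ids:
            fh.write(str(l) + "\n")
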