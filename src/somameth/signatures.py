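"""96-context mutational spectra and SBS signature cosine matching.

Single-base substitutions are collapsed onto the pyrimidine strand and
binned by substitution class (C>A, C>G, C>T, T>A, T>C, T>G) crossed with
the 5' and 3' flanking bases, giving the canonical 96 trinucleotide
contexts in COSMIC order (A[C>A]A ... T[T>G]T).  A cohort spectrum is
matched against a catalog of signature probability vectors by cosine
similarity; the study design only requires similarity ranking, not
exposure refitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .variants import _COMPLEMENT, CohortVariantTable, collapse_substitution

BASES = ("A", "C", "G", "T")

#: canonical COSMIC-ordered 96 context labels
CONTEXT_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
    for five in BASES
    for three in BASES
)

_CONTEXT_INDEX = {label: i for i, label in enumerate(CONTEXT_96)}


class ContextError(ValueError):
    """Raised when a variant's reference context cannot be resolved."""


ReferenceLookup = Callable[[str, int], str]
"""Callable returning the reference base (A/C/G/T) at a 1-based position."""


class FastaLookup:
    """Reference-base lookup backed by an indexed FASTA via pyfaidx."""

    def __init__(self, path: str | Path):
        from pyfaidx import Fasta

        self._fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)

    def __call__(self, chrom: str, pos: int) -> str:
        try:
            return str(self._fa[chrom][pos - 1])
        except (KeyError, IndexError) as exc:
            raise ContextError(f"no reference base at {chrom}:{pos}") from exc


def trinucleotide_context(
    chrom: str, pos: int, ref: str, alt: str, reference_lookup: ReferenceLookup
) -> tuple[str, str, str]:
    """Resolve (substitution class, 5' base, 3' base) on the pyrimidine strand.

    Purine-reference variants are reverse-complemented, which also swaps
    the flanking bases.  Raises :class:`ContextError` if the reference
    base at ``pos`` disagrees with ``ref``.
    """
    base = reference_lookup(chrom, pos)
    if base != ref:
        raise ContextError(
            f"reference mismatch at {chrom}:{pos}: expected {ref}, found {base}"
        )
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ContextError(f"non-ACGT allele at {chrom}:{pos}: {ref}>{alt}")
    left = reference_lookup(chrom, pos - 1)
    right = reference_lookup(chrom, pos + 1)
    if left not in _COMPLEMENT or right not in _COMPLEMENT:
        raise ContextError(f"non-ACGT flanking base at {chrom}:{pos}")
    sub = collapse_substitution(ref, alt)
    if ref in "CT":
        return sub, left, right
    return sub, _COMPLEMENT[right], _COMPLEMENT[left]


def context_label(sub: str, five: str, three: str) -> str:
    return f"{five}[{sub}]{three}"


@dataclass
class TrinucleotideSpectrum:
    """Counts of SNVs over the 96 pyrimidine-strand trinucleotide contexts."""

    counts: np.ndarray  # length 96, non-negative integers
    n_skipped: int = 0  # variants dropped for context errors

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (96,):
            raise ValueError("spectrum requires exactly 96 bins")
        if np.any(self.counts < 0):
            raise ValueError("spectrum counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def fractions(self) -> np.ndarray:
        """Percentage-normalised view (sums to 100)."""
        return 100.0 * self.counts / self.counts.sum()

    def to_frame(self, name: str = "count") -> pd.DataFrame:
        return pd.DataFrame({"context": CONTEXT_96, name: self.counts})


@dataclass
class SignatureCatalog:
    """Named probability vectors over the 96 contexts, COSMIC bin order."""

    profiles: pd.DataFrame  # index CONTEXT_96, one column per signature

    def __post_init__(self) -> None:
        df = self.profiles
        if set(df.index) != set(CONTEXT_96):
            missing = sorted(set(CONTEXT_96) - set(df.index))[:3]
            raise ValueError(f"catalog bins do not cover the 96 contexts "
                             f"(e.g. missing {missing})")
        # canonicalize row order regardless of file order
        self.profiles = df.loc[list(CONTEXT_96)].astype(float)
        sums = self.profiles.sum(axis=0)
        if np.any(self.profiles.values < 0):
            raise ValueError("catalog probabilities must be non-negative")
        bad = sums[(sums - 1.0).abs() > 1e-6]
        if len(bad):
            raise ValueError(
                f"signature columns must sum to 1 (offenders: {list(bad.index)[:3]})"
            )
        if self.profiles.columns.duplicated().any():
            raise ValueError("duplicate signature names in catalog")

    @property
    def names(self) -> list[str]:
        return list(self.profiles.columns)

    def vector(self, name: str) -> np.ndarray:
        return self.profiles[name].to_numpy()


def read_catalog(path: str | Path) -> SignatureCatalog:
    """Load a signature catalog TSV (first column = context label)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SignatureCatalog(df)


def write_catalog(catalog: SignatureCatalog, path: str | Path) -> None:
    out = catalog.profiles.copy()
    out.index.name = "context"
    out.to_csv(path, sep="\t")


def build_spectrum(
    table: CohortVariantTable,
    group: str,
    reference_lookup: ReferenceLookup | None = None,
    context_column: str = "ref_context",
) -> TrinucleotideSpectrum:
    """Aggregate a group's SNVs into a 96-context spectrum.

    Contexts come either from ``reference_lookup`` (FASTA-backed or any
    callable) or, when that is None, from a per-variant trinucleotide
    context column giving the reference-strand 3-mer centred on the
    variant.  Non-SNV records are ignored; SNVs whose context cannot be
    resolved are skipped and counted in ``n_skipped``.
    """
    snv = table.snvs(group)
    if not len(snv):
        raise ValueError(
            f"group {group!r} has no SNVs; an empty spectrum is undefined"
        )
    counts = np.zeros(96, dtype=np.int64)
    skipped = 0
    if reference_lookup is None:
        if context_column not in snv.columns:
            raise ValueError(
                f"no reference lookup given and column {context_column!r} absent"
            )
        for ref, alt, ctx in zip(snv["ref"], snv["alt"], snv[context_column]):
            try:
                counts[_context_bin_from_3mer(ctx, ref, alt)] += 1
            except ContextError:
                skipped += 1
    else:
        for chrom, pos, ref, alt in zip(
            snv["chrom"], snv["pos"], snv["ref"], snv["alt"]
        ):
            try:
                sub, five, three = trinucleotide_context(
                    chrom, int(pos), ref, alt, reference_lookup
                )
            except ContextError:
                skipped += 1
                continue
            counts[_CONTEXT_INDEX[context_label(sub, five, three)]] += 1
    return TrinucleotideSpectrum(counts, n_skipped=skipped)


def _context_bin_from_3mer(ctx: str, ref: str, alt: str) -> int:
    if not isinstance(ctx, str) or len(ctx) != 3:
        raise ContextError(f"malformed context {ctx!r}")
    left, mid, right = ctx
    if mid != ref:
        raise ContextError(f"context middle base {mid!r} does not match ref {ref!r}")
    if any(b not in _COMPLEMENT for b in (left, mid, right)) or alt not in _COMPLEMENT:
        raise ContextError(f"non-ACGT base in context {ctx!r} or alt {alt!r}")
    sub = collapse_substitution(ref, alt)
    if ref in "CT":
        five, three = left, right
    else:
        five, three = _COMPLEMENT[right], _COMPLEMENT[left]
    return _CONTEXT_INDEX[context_label(sub, five, three)]


def cosine_similarity(a, b) -> float:
    """Cosine similarity of two non-negative 96-bin vectors, in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("cosine similarity requires non-negative vectors")
    return float(np.dot(a, b) / (na * nb))


def best_match(
    spectrum: TrinucleotideSpectrum, catalog: SignatureCatalog
) -> pd.DataFrame:
    """Rank catalog signatures by cosine similarity to a spectrum.

    Descending by cosine; exact ties are broken by signature name
    ascending and flagged in a ``tied`` column.
    """
    if not catalog.names:
        raise ValueError("catalog is empty")
    sims = {
        name: cosine_similarity(spectrum.counts, catalog.vector(name))
        for name in catalog.names
    }
    out = pd.DataFrame(
        {"signature": list(sims.keys()), "cosine": list(sims.values())}
    ).sort_values(["cosine", "signature"], ascending=[False, True])
    out["tied"] = out["cosine"].duplicated(keep=False)
    return out.reset_index(drop=True)


def synthetic_catalog() -> SignatureCatalog:
    """Small synthetic signature catalog for tests and simulations.

    These are hand-built stand-ins that echo the qualitative shapes of the
    COSMIC signatures they are named after — SBS1 concentrates C>T at
    NpCpG (5-methylcytosine deamination), SBS6 spreads C>T over non-CpG
    contexts (mismatch-repair deficiency), SBS5 is flat-ish with a T>C
    tilt — plus a uniform signature and a C>A-rich one.  They are NOT the
    COSMIC profiles; real analyses should load a published catalog file.
    """
    n = 96
    flat = np.full(n, 1.0 / n)

    def _mask(sub: str, three: str | None = None, exclude_three: str | None = None):
        m = np.zeros(n)
        for i, label in enumerate(CONTEXT_96):
            s = label[2:5]
            t = label[6]
            if s != sub:
                continue
            if three is not None and t != three:
                continue
            if exclude_three is not None and t == exclude_three:
                continue
            m[i] = 1.0
        return m / m.sum()

    sbs1 = 0.80 * _mask("C>T", three="G") + 0.20 * flat
    sbs6 = 0.75 * _mask("C>T", exclude_three="G") + 0.25 * flat
    sbs5 = 0.50 * _mask("T>C") + 0.50 * flat
    flat96 = flat.copy()
    syn_ca = 0.70 * _mask("C>A") + 0.30 * flat

    df = pd.DataFrame(
        {
            "SBS1": sbs1,
            "SBS5": sbs5,
            "SBS6": sbs6,
            "Flat96": flat96,
            "SynCA": syn_ca,
        },
        index=list(CONTEXT_96),
    )
    return SignatureCatalog(df)
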