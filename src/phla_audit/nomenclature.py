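"""HLA class I allele nomenclature: parsing and two-field canonicalization.

Allele names arrive in many shapes — ``HLA-A*01:01:01:01``, ``A*01:01:01N``,
``A*01:01`` — but population frequency tables and pHLA datasets are joined on
the two-field (allele group + specific protein) form, e.g. ``A*01:01``.
Higher-resolution fields describe synonymous or non-coding variation and are
truncated; expression suffixes (N, L, Q, ...) are dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

#: Class I loci handled by the audit.
CLASS_I_LOCI = ("A", "B", "C")

#: Sentinel allele carrying residual (unreported) frequency mass for a locus.
#: It never matches a dataset pair, so it can never be "hit".
OTHER_ALLELE = "OTHER"

_ALLELE_RE = re.compile(
    r"^(?:HLA-)?(?P<locus>[A-Za-z]{1,4}\d?)\*"
    r"(?P<fields>\d{1,3}(?::\d{1,3})+)"
    r"(?P<suffix>[NLSCAQ]?)$"
)


class AlleleParseError(ValueError):
    """Raised when an allele name cannot be canonicalized."""


@dataclass(frozen=True, order=True)
class AlleleName:
    """Two-field canonical allele name: locus, allele group, specific protein."""

    locus: str
    group: str
    protein: str

    def __str__(self) -> str:
        return f"{self.locus}*{self.group}:{self.protein}"


def canonicalize_allele(name: str, loci: tuple[str, ...] = CLASS_I_LOCI) -> AlleleName:
    """Parse an allele name and truncate it to the two-field form.

    Parameters
    ----------
    name:
        Raw allele name, with or without the ``HLA-`` prefix, with two to four
        colon-separated numeric fields and an optional expression suffix.
    loci:
        Accepted loci; anything else is rejected.

    Returns
    -------
    AlleleName
        The canonical two-field name.

    Raises
    ------
    AlleleParseError
        If the name is unparseable or names a locus outside ``loci``. The
        offending token is reported in the message.

    Examples
    --------
    >>> str(canonicalize_allele("HLA-A*01:01:01:01"))
    'A*01:01'
    """
    if not isinstance(name, str):
        raise AlleleParseError(f"allele name must be a string, got {name!r}")
    token = name.strip()
    m = _ALLELE_RE.match(token)
    if m is None:
        raise AlleleParseError(f"unparseable allele name: {token!r}")
    locus = m.group("locus").upper()
    if locus not in loci:
        raise AlleleParseError(f"unknown locus {locus!r} in allele name {token!r}")
    fields = m.group("fields").split(":")
    group, protein = fields[0], fields[1]
    # zero-pad to the conventional two digits so A*1:1 and A*01:01 unify
    return AlleleName(locus=locus, group=group.zfill(2), protein=protein.zfill(2))


def canonical_str(name: str, loci: tuple[str, ...] = CLASS_I_LOCI) -> str:
    """Canonicalize and render as a string (convenience for tabular code)."""
    return str(canonicalize_allele(name, loci))


def allele_locus(allele: str) -> str:
    """Locus prefix of a canonical allele string (``A*02:01`` -> ``A``)."""
    return allele.split("*", 1)[0]
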