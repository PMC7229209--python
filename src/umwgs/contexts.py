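"""Canonical substitution-class definitions.

Single-base substitutions are binned into the 96 pyrimidine-centred
trinucleotide classes (``A[C>A]A`` ... ``T[T>G]T``) and doublet-base
substitutions into the 78 canonical dinucleotide classes (``AC>CA`` ...
``TT>GG``).  Purine-centred events are mapped onto the canonical classes by
reverse complementation, so catalogues are strand-agnostic.
"""

from __future__ import annotations

import re

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

BASES = "ACGT"
PYRIMIDINE_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 canonical SBS classes, substitution-major order.
SBS96_CLASSES: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in PYRIMIDINE_SUBS
    for five in BASES
    for three in BASES
)

_SBS96_INDEX = {c: i for i, c in enumerate(SBS96_CLASSES)}

_CTX_RE = re.compile(r"^([ACGT])\[([ACGT])>([ACGT])\]([ACGT])$")


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def normalise_sbs_context(context: str) -> str:
    """Map a trinucleotide context string to its pyrimidine-centred class.

    ``A[G>A]C`` (purine-centred) becomes ``G[C>T]T``.  Raises ``ValueError``
    on malformed strings or identity substitutions.
    """
    m = _CTX_RE.match(context)
    if not m:
        raise ValueError(f"malformed trinucleotide context: {context!r}")
    five, ref, alt, three = m.groups()
    if ref == alt:
        raise ValueError(f"identity substitution in context: {context!r}")
    if ref in "CT":
        cls = f"{five}[{ref}>{alt}]{three}"
    else:
        cls = f"{_COMPLEMENT[three]}[{_COMPLEMENT[ref]}>{_COMPLEMENT[alt]}]{_COMPLEMENT[five]}"
    if cls not in _SBS96_INDEX:  # pragma: no cover - defensive
        raise ValueError(f"context {context!r} outside the 96 canonical classes")
    return cls


def sbs_index(context: str) -> int:
    """Index of a (possibly purine-centred) context in ``SBS96_CLASSES``."""
    return _SBS96_INDEX[normalise_sbs_context(context)]


# --- doublet classes -------------------------------------------------------

#: Reference dinucleotides retained after reverse-complement collapsing.
DBS_CANONICAL_REFS = ("AC", "AT", "CC", "CG", "CT", "GC", "TA", "TC", "TG", "TT")
_DBS_PALINDROMIC = frozenset({"AT", "CG", "GC", "TA"})


def _dbs_classes() -> tuple[str, ...]:
    classes: list[str] = []
    for ref in DBS_CANONICAL_REFS:
        alts = set()
        for a in BASES:
            for b in BASES:
                alt = a + b
                if a == ref[0] or b == ref[1]:
                    continue
                if ref in _DBS_PALINDROMIC:
                    alt = min(alt, revcomp(alt))
                alts.add(alt)
        classes.extend(f"{ref}>{alt}" for alt in sorted(alts))
    return tuple(classes)


#: The 78 canonical DBS classes.
DBS78_CLASSES: tuple[str, ...] = _dbs_classes()

_DBS78_INDEX = {c: i for i, c in enumerate(DBS78_CLASSES)}

_DBS_RE = re.compile(r"^([ACGT]{2})>([ACGT]{2})$")


def normalise_dbs_context(context: str) -> str:
    """Map a dinucleotide substitution (``REF>ALT``) to its canonical class."""
    m = _DBS_RE.match(context)
    if not m:
        raise ValueError(f"malformed doublet substitution: {context!r}")
    ref, alt = m.groups()
    if ref[0] == alt[0] or ref[1] == alt[1]:
        raise ValueError(f"doublet {context!r} leaves one position unchanged")
    if ref not in DBS_CANONICAL_REFS:
        ref, alt = revcomp(ref), revcomp(alt)
    if ref in _DBS_PALINDROMIC:
        alt = min(alt, revcomp(alt))
    cls = f"{ref}>{alt}"
    if cls not in _DBS78_INDEX:  # pragma: no cover - defensive
        raise ValueError(f"doublet {context!r} outside the 78 canonical classes")
    return cls


def dbs_index(context: str) -> int:
    return _DBS78_INDEX[normalise_dbs_context(context)]
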