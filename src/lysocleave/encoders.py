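"""Per-residue feature encoders.

A protein sequence (optionally carrying per-residue secondary-structure and
solvent-accessibility annotations) is translated into up to five parallel
character tracks:

========== ========================= ======
feature    alphabet                  size
========== ========================= ======
aa         the 20 canonical residues 20
charge     ``+`` ``N`` ``-``         3
hydropathy ``ζ`` ``M`` ``Φ``         3
ss         ``C`` ``E`` ``H``         3
rsa        ``0`` … ``9``             10
========== ========================= ======

The charge and hydropathy class tables are shipped as editable TSV files
under :mod:`lysocleave.data`; they are reconstructions of a vendor property
table and can be overridden by the caller.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, Optional

from .errors import AnnotationMismatchError, InvalidAlphabetError

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
CHARGE_ALPHABET = "+N-"
HYDROPATHY_ALPHABET = "ζMΦ"
SS_ALPHABET = "CEH"
RSA_ALPHABET = "0123456789"

#: residues tolerated only under the permissive prediction flag
NONCANONICAL = set("BJOUXZ")

FEATURES = ("aa", "charge", "hydropathy", "ss", "rsa")

ALPHABETS: Dict[str, str] = {
    "aa": AA_ALPHABET,
    "charge": CHARGE_ALPHABET,
    "hydropathy": HYDROPATHY_ALPHABET,
    "ss": SS_ALPHABET,
    "rsa": RSA_ALPHABET,
}

#: window geometry: 8 residues P4..P4', scissile bond between P1 and P1'
WINDOW_SIZE = 8
WINDOW_OFFSET = 3  # residues N-terminal of P1 inside the window

POSITION_LABELS = ("P4", "P3", "P2", "P1", "P1'", "P2'", "P3'", "P4'")


def _load_class_table(name: str) -> Dict[str, str]:
    path = resources.files("lysocleave.data").joinpath(name)
    with path.open(encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    return {r["residue"]: r["class"] for r in rows}


CHARGE_CLASSES: Dict[str, str] = _load_class_table("charge_classes.tsv")
HYDROPATHY_CLASSES: Dict[str, str] = _load_class_table("hydropathy_classes.tsv")


@dataclass(frozen=True)
class AnnotatedSequence:
    """A protein sequence plus optional structure/accessibility tracks.

    Parameters
    ----------
    id : str
        Sequence identifier (FASTA header word).
    residues : str
        Amino-acid sequence, upper case.
    ss : str, optional
        Secondary structure per residue over ``{C, E, H}``.
    rsa : str, optional
        Solvent-accessibility digit per residue, ``0`` (buried) to ``9``
        (exposed).
    permissive : bool
        Accept the non-canonical letters ``BJOUXZ`` in ``residues``.
        Windows containing them are skipped during scoring.
    """

    id: str
    residues: str
    ss: Optional[str] = None
    rsa: Optional[str] = None
    permissive: bool = field(default=False, compare=False)

    def __post_init__(self):
        if not self.residues:
            raise InvalidAlphabetError("empty sequence %r" % self.id)
        allowed = set(AA_ALPHABET) | (NONCANONICAL if self.permissive else set())
        for i, ch in enumerate(self.residues):
            if ch not in allowed:
                raise InvalidAlphabetError(
                    f"sequence {self.id!r}: illegal residue {ch!r} at position {i + 1}",
                    position=i,
                    character=ch,
                )
        for track, alphabet, label in ((self.ss, SS_ALPHABET, "ss"),
                                       (self.rsa, RSA_ALPHABET, "rsa")):
            if track is None:
                continue
            if len(track) != len(self.residues):
                raise AnnotationMismatchError(
                    f"sequence {self.id!r}: {label} length {len(track)} != "
                    f"sequence length {len(self.residues)}"
                )
            for i, ch in enumerate(track):
                if ch not in alphabet:
                    raise InvalidAlphabetError(
                        f"sequence {self.id!r}: illegal {label} character "
                        f"{ch!r} at position {i + 1}",
                        position=i,
                        character=ch,
                    )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def annotated(self) -> bool:
        return self.ss is not None and self.rsa is not None

    def slice(self, start: int, end: int, new_id: Optional[str] = None) -> "AnnotatedSequence":
        """Return the 1-based inclusive subsequence with annotations sliced along."""
        if not (1 <= start <= end <= len(self)):
            raise IndexError(f"slice [{start}, {end}] outside sequence of length {len(self)}")
        return AnnotatedSequence(
            id=new_id or f"{self.id}|{start}-{end}",
            residues=self.residues[start - 1:end],
            ss=None if self.ss is None else self.ss[start - 1:end],
            rsa=None if self.rsa is None else self.rsa[start - 1:end],
            permissive=self.permissive,
        )


@dataclass(frozen=True)
class FeatureTrack:
    """One encoded character track, parallel to its source sequence."""

    feature: str
    alphabet: str
    encoded: str

    def __post_init__(self):
        if self.feature not in FEATURES:
            raise ValueError(f"unknown feature {self.feature!r}")
        for i, ch in enumerate(self.encoded):
            if ch not in self.alphabet:
                raise InvalidAlphabetError(
                    f"{self.feature} track: illegal character {ch!r} at position {i + 1}",
                    position=i,
                    character=ch,
                )

    def __len__(self) -> int:
        return len(self.encoded)


def _encode_classes(residues: str, table: Dict[str, str], feature: str,
                    alphabet: str) -> FeatureTrack:
    out = []
    for i, ch in enumerate(residues):
        try:
            out.append(table[ch])
        except KeyError:
            raise InvalidAlphabetError(
                f"cannot {feature}-encode residue {ch!r} at position {i + 1}",
                position=i,
                character=ch,
            ) from None
    return FeatureTrack(feature=feature, alphabet=alphabet, encoded="".join(out))


def encode_charge(residues: str, table: Optional[Dict[str, str]] = None) -> FeatureTrack:
    """Encode a residue string into charge classes ``+``/``N``/``-``.

    D and E are negative; K, R and H positive; everything else neutral
    (per the packaged, overridable class table).
    """
    return _encode_classes(residues, table or CHARGE_CLASSES, "charge", CHARGE_ALPHABET)


def encode_hydropathy(residues: str, table: Optional[Dict[str, str]] = None) -> FeatureTrack:
    """Encode a residue string into hydropathy classes ``ζ``/``M``/``Φ``
    (hydrophilic / neutral / hydrophobic)."""
    return _encode_classes(residues, table or HYDROPATHY_CLASSES, "hydropathy",
                           HYDROPATHY_ALPHABET)


def attach_structure(seq: AnnotatedSequence, ss: str, rsa: str) -> AnnotatedSequence:
    """Return ``seq`` with secondary-structure and accessibility tracks attached.

    Both tracks are validated for length and alphabet.
    """
    return replace(seq, ss=ss, rsa=rsa)


def encode_tracks(seq: AnnotatedSequence, features=FEATURES) -> Dict[str, FeatureTrack]:
    """Encode all requested feature tracks for one sequence.

    Raises
    ------
    MissingAnnotationError
        If ``ss`` or ``rsa`` is requested but the sequence carries no
        annotation for it.
    """
    from .errors import MissingAnnotationError

    tracks: Dict[str, FeatureTrack] = {}
    for feature in features:
        if feature == "aa":
            # permissive sequences may hold non-canonical letters; the aa
            # track keeps them verbatim and window extraction filters them
            tracks["aa"] = (_unchecked_track("aa", AA_ALPHABET, seq.residues)
                            if seq.permissive
                            else FeatureTrack("aa", AA_ALPHABET, seq.residues))
        elif feature == "charge":
            tracks["charge"] = encode_charge(seq.residues) if not seq.permissive \
                else _encode_permissive(seq.residues, CHARGE_CLASSES, "charge", CHARGE_ALPHABET)
        elif feature == "hydropathy":
            tracks["hydropathy"] = encode_hydropathy(seq.residues) if not seq.permissive \
                else _encode_permissive(seq.residues, HYDROPATHY_CLASSES, "hydropathy",
                                        HYDROPATHY_ALPHABET)
        elif feature == "ss":
            if seq.ss is None:
                raise MissingAnnotationError(
                    f"sequence {seq.id!r} has no secondary-structure track")
            tracks["ss"] = FeatureTrack("ss", SS_ALPHABET, seq.ss)
        elif feature == "rsa":
            if seq.rsa is None:
                raise MissingAnnotationError(
                    f"sequence {seq.id!r} has no solvent-accessibility track")
            tracks["rsa"] = FeatureTrack("rsa", RSA_ALPHABET, seq.rsa)
        else:
            raise ValueError(f"unknown feature {feature!r}")
    return tracks


def _unchecked_track(feature: str, alphabet: str, encoded: str) -> FeatureTrack:
    t = FeatureTrack.__new__(FeatureTrack)
    object.__setattr__(t, "feature", feature)
    object.__setattr__(t, "alphabet", alphabet)
    object.__setattr__(t, "encoded", encoded)
    return t


def _encode_permissive(residues, table, feature, alphabet):
    # non-canonical residues become '?'; windows touching them are skipped
    encoded = "".join(table.get(ch, "?") for ch in residues)
    return _unchecked_track(feature, alphabet, encoded)


_TAIL = WINDOW_SIZE - WINDOW_OFFSET - 1  # residues needed after P1 (4)


def window_positions(length: int):
    """All 1-based P1 indices with a full 8-character window, ascending."""
    return range(WINDOW_OFFSET + 1, length - _TAIL + 1)


def has_full_window(p1: int, length: int) -> bool:
    return WINDOW_OFFSET + 1 <= p1 <= length - _TAIL


def extract_window(track, p1: int) -> Optional[str]:
    """Return the 8-character P4..P4' window centred on the bond after ``p1``.

    ``track`` may be a :class:`FeatureTrack` or a plain string. Returns
    ``None`` when the window does not fit entirely inside the sequence.

    Raises
    ------
    IndexError
        If ``p1`` lies outside the sequence altogether.
    """
    encoded = track.encoded if isinstance(track, FeatureTrack) else track
    length = len(encoded)
    if not (1 <= p1 <= length):
        raise IndexError(f"p1={p1} outside sequence of length {length}")
    if not has_full_window(p1, length):
        return None
    start = p1 - 1 - WINDOW_OFFSET
    return encoded[start:start + WINDOW_SIZE]
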