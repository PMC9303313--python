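"""Gapmer sequence/chemistry data model and basic sequence utilities.

A gapmer ASO is a short single-stranded DNA oligonucleotide whose central
"gap" (plain DNA, phosphorothioate backbone) is flanked by high-affinity
"wings" (LNA by default).  The gap supports RNase H cleavage of the bound
RNA; the wings boost affinity.  Nucleobase modifications -- analogs of C, T
or G substituted at single gap positions -- are modelled as *annotations*:
all derivatives in the registry retain the Watson-Crick pairing face of
their parent base, so the search sequence is always the plain-letter
sequence and complementarity scanning is unaffected by chemistry.

Modification positions are 1-based indices into the full ASO sequence and
must fall inside the gap region.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

__all__ = [
    "AlphabetError",
    "RegistryError",
    "ValidationError",
    "NucleobaseMod",
    "ModRegistry",
    "DEFAULT_REGISTRY",
    "GapmerASO",
    "normalize_sequence",
    "reverse_complement",
    "count_motifs",
    "parse_gapmer",
    "format_gapmer",
    "parse_mod_token",
    "apply_modification",
    "validate_design",
]


class AlphabetError(ValueError):
    """A sequence contains characters outside the DNA alphabet."""


class RegistryError(KeyError):
    """A nucleobase-modification code is not registered."""


class ValidationError(ValueError):
    """A gapmer or modification violates a structural invariant."""


_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_DNA_RE = re.compile(r"^[ACGT]*$")


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and convert RNA U to DNA T.

    Raises :class:`AlphabetError` for any residue outside {A, C, G, T, U}.
    """
    s = seq.upper().replace("U", "T")
    if not _DNA_RE.match(s):
        bad = sorted(set(s) - set("ACGT"))
        raise AlphabetError(f"non-ACGTU characters in sequence: {bad}")
    return s


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of a DNA string.

    Used to turn an ASO sequence into the pattern searched along the
    transcript *sense* strand (ASO:RNA hybridization has fixed orientation).
    """
    if not _DNA_RE.match(seq):
        bad = sorted(set(seq) - set("ACGT"))
        raise AlphabetError(f"non-ACGT characters in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def count_motifs(seq: str, motifs: Iterable[str] = ("TGC", "TCC")) -> dict[str, int]:
    """Count (possibly overlapping) occurrences of each motif in ``seq``.

    TGC and TCC are the consensus trinucleotides associated with gapmer
    hepatotoxicity; any user-supplied motif list (e.g. dinucleotide sets)
    works the same way.  Overlapping occurrences are counted: every start
    offset ``i`` with ``seq[i:i+len(m)] == m`` contributes one.
    """
    s = normalize_sequence(seq)
    counts: dict[str, int] = {}
    for motif in motifs:
        m = normalize_sequence(motif)
        if not m:
            raise ValueError("empty motif")
        counts[motif] = sum(1 for i in range(len(s) - len(m) + 1) if s[i : i + len(m)] == m)
    return counts


@dataclass(frozen=True)
class NucleobaseMod:
    """One nucleobase modification: a registered analog at a 1-based position.

    ``base_letter`` is the parent base the analog replaces; it must equal the
    sequence letter at ``position``.  ``novel`` marks derivatives first made
    for this class of study (G4-G7 in the default registry).
    """

    code: str
    base_letter: str
    position: int
    chemistry_name: Optional[str] = None
    novel: bool = False


class ModRegistry:
    """Registry of nucleobase-modification codes.

    Maps a short code like ``C1`` or ``G8`` to its parent base letter, an
    optional chemistry name, and a novelty flag.  Codes must be unique and
    the base letter one of A/C/G/T (A is allowed for user extensions even
    though the default registry only modifies C, T and G).
    """

    def __init__(self) -> None:
        self._entries: dict[str, tuple[str, Optional[str], bool]] = {}

    def register(
        self,
        code: str,
        base_letter: str,
        chemistry_name: Optional[str] = None,
        novel: bool = False,
    ) -> None:
        if base_letter not in "ACGT":
            raise ValueError(f"base_letter must be one of A/C/G/T, got {base_letter!r}")
        if code in self._entries:
            raise ValueError(f"duplicate modification code {code!r}")
        self._entries[code] = (base_letter, chemistry_name, novel)

    def __contains__(self, code: str) -> bool:
        return code in self._entries

    def codes(self) -> list[str]:
        return list(self._entries)

    def base_letter(self, code: str) -> str:
        return self._get(code)[0]

    def chemistry_name(self, code: str) -> Optional[str]:
        return self._get(code)[1]

    def is_novel(self, code: str) -> bool:
        return self._get(code)[2]

    def _get(self, code: str) -> tuple[str, Optional[str], bool]:
        try:
            return self._entries[code]
        except KeyError:
            raise RegistryError(f"unknown modification code {code!r}") from None

    def make_mod(self, code: str, position: int) -> NucleobaseMod:
        """Instantiate a :class:`NucleobaseMod` for a registered code."""
        base, chem, novel = self._get(code)
        return NucleobaseMod(code=code, base_letter=base, position=position,
                             chemistry_name=chem, novel=novel)


def _default_registry() -> ModRegistry:
    # 17 derivatives of C, T and G; modification sites (5-/2-position of
    # pyrimidines, 7-/8-position of purines) avoid the pairing face, so all
    # retain parent-letter Watson-Crick pairing.  Chemistry names are known
    # for the three derivatives most used in combination.
    reg = ModRegistry()
    reg.register("C1", "C", "5-hydroxycytosine")
    reg.register("C2", "C")
    reg.register("C3", "C")
    reg.register("C4", "C")
    reg.register("T1", "T", "2-thiothymine")
    reg.register("T2", "T")
    reg.register("T3", "T")
    reg.register("T4", "T")
    reg.register("T5", "T")
    reg.register("G1", "G", "8-bromoguanine")
    reg.register("G2", "G")
    reg.register("G3", "G")
    reg.register("G4", "G", novel=True)
    reg.register("G5", "G", novel=True)
    reg.register("G6", "G", novel=True)
    reg.register("G7", "G", novel=True)
    reg.register("G8", "G")
    return reg


DEFAULT_REGISTRY = _default_registry()


@dataclass(frozen=True)
class GapmerASO:
    """An LNA gapmer ASO: wing5 | gap | wing3 over a plain DNA sequence.

    Invariants (checked by :func:`validate_design` / ``validate()``):

    * ``wing5_len + gap_len + wing3_len == len(sequence)``;
    * every modification position lies in the gap (1-based, full-sequence
      indexing);
    * each modification's registered base letter equals the sequence letter
      at its position.
    """

    id: str
    sequence: str
    wing5_len: int = 2
    gap_len: int = 10
    wing3_len: int = 2
    backbone: str = "PS"
    wing_chemistry: str = "LNA"
    modifications: tuple[NucleobaseMod, ...] = field(default_factory=tuple)

    @property
    def gap_start(self) -> int:
        """First gap position, 1-based."""
        return self.wing5_len + 1

    @property
    def gap_end(self) -> int:
        """Last gap position, 1-based."""
        return self.wing5_len + self.gap_len

    def gap_positions(self) -> range:
        """1-based positions of the gap region."""
        return range(self.gap_start, self.gap_end + 1)

    def validate(self) -> list[str]:
        return validate_design(self)

    def with_modification(self, mod: NucleobaseMod) -> "GapmerASO":
        return apply_modification(self, mod)

    def derived_name(self) -> str:
        """Display name ``{id}-{code}-{pos}`` for a singly modified gapmer
        whose id is the bare parent label; otherwise the id itself."""
        if len(self.modifications) == 1:
            m = self.modifications[0]
            suffix = f"-{m.code}-{m.position}"
            if not self.id.endswith(suffix):
                return self.id + suffix
        return self.id


def validate_design(aso: GapmerASO, registry: ModRegistry = DEFAULT_REGISTRY) -> list[str]:
    """Check all structural invariants; return human-readable violations.

    Violations are returned (not raised) so a whole table of designs can be
    audited in one pass.
    """
    violations: list[str] = []
    n = len(aso.sequence)
    if not _DNA_RE.match(aso.sequence) or n == 0:
        violations.append(f"{aso.id}: sequence must be non-empty over A/C/G/T")
        return violations
    if aso.wing5_len < 0 or aso.wing3_len < 0 or aso.gap_len < 1:
        violations.append(f"{aso.id}: wing lengths must be >=0 and gap length >=1")
    if aso.wing5_len + aso.gap_len + aso.wing3_len != n:
        violations.append(
            f"{aso.id}: design {aso.wing5_len}-{aso.gap_len}-{aso.wing3_len} "
            f"sums to {aso.wing5_len + aso.gap_len + aso.wing3_len}, sequence length is {n}"
        )
    seen_positions: set[int] = set()
    for mod in aso.modifications:
        if mod.code not in registry:
            violations.append(f"{aso.id}: unregistered modification code {mod.code!r}")
            continue
        if mod.position in seen_positions:
            violations.append(f"{aso.id}: duplicate modification at position {mod.position}")
        seen_positions.add(mod.position)
        if not (1 <= mod.position <= n):
            violations.append(f"{aso.id}: modification position {mod.position} outside sequence")
            continue
        if not (aso.gap_start <= mod.position <= aso.gap_end):
            violations.append(
                f"{aso.id}: modification {mod.code} at position {mod.position} "
                f"is outside the gap (positions {aso.gap_start}-{aso.gap_end})"
            )
        letter = aso.sequence[mod.position - 1]
        if registry.base_letter(mod.code) != letter:
            violations.append(
                f"{aso.id}: {mod.code} replaces {registry.base_letter(mod.code)} "
                f"but position {mod.position} holds {letter}"
            )
    return violations


def apply_modification(
    aso: GapmerASO, mod: NucleobaseMod, registry: ModRegistry = DEFAULT_REGISTRY
) -> GapmerASO:
    """Annotate ``aso`` with one nucleobase modification.

    The base sequence string is unchanged: modified nucleobases keep the
    Watson-Crick identity of the parent letter, so complementarity searches
    run on the plain sequence.  Raises :class:`ValidationError` on duplicate
    position, position outside the gap, or base-letter mismatch; raises
    :class:`RegistryError` for an unknown code.
    """
    if mod.code not in registry:
        raise RegistryError(f"unknown modification code {mod.code!r}")
    if any(m.position == mod.position for m in aso.modifications):
        raise ValidationError(f"{aso.id}: duplicate modification at position {mod.position}")
    out = replace(aso, modifications=aso.modifications + (mod,))
    problems = validate_design(out, registry)
    if problems:
        raise ValidationError("; ".join(problems))
    return out


_MOD_NAME_RE = re.compile(r"^(?P<parent>.+)-(?P<code>[A-Z]\d+)-(?P<pos>\d+)$")
_MOD_TOKEN_RE = re.compile(r"^(?P<code>[A-Z]\d+)@(?P<pos>\d+)$")


def parse_mod_token(token: str, registry: ModRegistry = DEFAULT_REGISTRY) -> NucleobaseMod:
    """Parse a ``CODE@POS`` token (e.g. ``C1@7``) into a NucleobaseMod."""
    m = _MOD_TOKEN_RE.match(token.strip())
    if not m:
        raise ValidationError(f"cannot parse modification token {token!r} (expected CODE@POS)")
    return registry.make_mod(m.group("code"), int(m.group("pos")))


def parse_gapmer(
    name: str,
    sequence: Optional[str] = None,
    *,
    wing5_len: int = 2,
    gap_len: Optional[int] = None,
    wing3_len: int = 2,
    backbone: str = "PS",
    wing_chemistry: str = "LNA",
    mods: str = "",
    parents: Optional[Mapping[str, GapmerASO]] = None,
    registry: ModRegistry = DEFAULT_REGISTRY,
) -> GapmerASO:
    """Build a validated :class:`GapmerASO` from a name and sequence.

    Two conventions are understood:

    * plain: ``parse_gapmer("TS1", "GTTATGCCACCCTA")`` with an optional
      ``mods`` string of semicolon-joined ``CODE@POS`` tokens;
    * derived naming: ``parse_gapmer("TS1-C1-7", parents={"TS1": ts1})``
      resolves ``{parent}-{code}-{position}`` against a parent gapmer and
      annotates the modification.

    Raises on unknown codes, base-letter mismatches and positions outside
    the gap.
    """
    match = _MOD_NAME_RE.match(name)
    if match and (parents is not None and match.group("parent") in parents):
        parent = parents[match.group("parent")]
        mod = registry.make_mod(match.group("code"), int(match.group("pos")))
        out = apply_modification(parent, mod, registry)
        return replace(out, id=name)
    if sequence is None:
        raise ValidationError(
            f"no sequence given for {name!r} and no parent resolves its name"
        )
    seq = normalize_sequence(sequence)
    if not seq:
        raise ValidationError("empty sequence")
    if gap_len is None:
        gap_len = len(seq) - wing5_len - wing3_len
    aso = GapmerASO(
        id=name,
        sequence=seq,
        wing5_len=wing5_len,
        gap_len=gap_len,
        wing3_len=wing3_len,
        backbone=backbone,
        wing_chemistry=wing_chemistry,
    )
    for token in filter(None, (t.strip() for t in mods.split(";"))):
        aso = apply_modification(aso, parse_mod_token(token, registry), registry)
    problems = validate_design(aso, registry)
    if problems:
        raise ValidationError("; ".join(problems))
    return aso


def format_gapmer(aso: GapmerASO) -> dict[str, str]:
    """Serialize a gapmer as a TSV-row dict (inverse of :func:`parse_gapmer`)."""
    return {
        "id": aso.id,
        "sequence": aso.sequence,
        "wing5": str(aso.wing5_len),
        "gap": str(aso.gap_len),
        "wing3": str(aso.wing3_len),
        "backbone": aso.backbone,
        "mods": ";".join(f"{m.code}@{m.position}" for m in aso.modifications),
    }
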