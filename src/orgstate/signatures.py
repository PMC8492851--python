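"""Gene signatures: the classical/basal-like PDAC subtype lists and cell-cycle lists.

The two 25-gene PDAC subtype signatures (classical and basal-like, after
Moffitt et al.) and the S-phase / G2M-phase marker lists are shipped as
editable plain-text fixtures (one gene symbol per line) under
``orgstate/data``.  Users can substitute their own lists with
:func:`load_signature`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import ConfigurationError, FormatError

__all__ = [
    "GeneSignature",
    "load_signature",
    "moffitt_classical",
    "moffitt_basal",
    "s_phase_signature",
    "g2m_signature",
]


@dataclass(frozen=True)
class GeneSignature:
    """A named, non-empty list of unique gene symbols."""

    name: str
    genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if len(self.genes) == 0:
            raise ConfigurationError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ConfigurationError(f"signature {self.name!r} has duplicate symbols")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


def load_signature(path: str | Path, name: str | None = None) -> GeneSignature:
    """Read a plain-text gene list (one symbol per line, '#' comments allowed)."""
    path = Path(path)
    genes = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return GeneSignature(name or path.stem, tuple(genes))


def _packaged(fname: str, name: str, expect: int | None = None) -> GeneSignature:
    with resources.as_file(resources.files("orgstate").joinpath("data", fname)) as p:
        sig = load_signature(p, name)
    if expect is not None and len(sig) != expect:
        raise FormatError(
            f"packaged signature {name!r} must contain {expect} genes, found {len(sig)}"
        )
    return sig


def moffitt_classical() -> GeneSignature:
    """The 25-gene classical-subtype signature (schema-checked)."""
    return _packaged("moffitt_classical.txt", "classical", expect=25)


def moffitt_basal() -> GeneSignature:
    """The 25-gene basal-like-subtype signature (schema-checked)."""
    return _packaged("moffitt_basal.txt", "basal", expect=25)


def s_phase_signature() -> GeneSignature:
    return _packaged("s_phase_genes.txt", "S")


def g2m_signature() -> GeneSignature:
    return _packaged("g2m_genes.txt", "G2M")
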