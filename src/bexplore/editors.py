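"""Base-editor definitions and the editor registry.

A base editor is described by its chemistry (which base it deaminates and
what that base becomes), the PAM its Cas module requires, the activity
window within the protospacer where deamination is efficient, and the
spacer length. Window positions are 1-based, counted 5'->3' from the
PAM-distal end of the protospacer — the convention used throughout the
base-editing literature.

Two widely used editors ship as defaults and are always available:

* ``BE3`` — cytosine base editor, C->T, PAM NGG, window 4-8, 20-nt spacer.
* ``ABE7.10`` — adenine base editor, A->G, PAM NGG, window 4-7, 20-nt spacer.

Both can be overridden (and new editors added) through a YAML config; the
registry, not the code, is authoritative for editor parameters.
"""

from __future__ import annotations

import io
from dataclasses import asdict, dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Union

import yaml

from .errors import ConfigError, EditorLookupError
from ._seq import is_iupac


class EditorClass(str, Enum):
    CBE = "CBE"
    ABE = "ABE"


#: Chemistry implied by the editor class: (target base, converted base).
_CLASS_CHEMISTRY = {EditorClass.CBE: ("C", "T"), EditorClass.ABE: ("A", "G")}


@dataclass(frozen=True)
class BaseEditor:
    """One base editor's chemistry and geometry.

    Attributes
    ----------
    name : short identifier, matched case-insensitively in the registry.
    editor_class : CBE (C->T) or ABE (A->G).
    target_base, converted_base : the deaminated base and its product.
    pam_pattern : IUPAC string located immediately 3' of the protospacer.
    window_start, window_end : 1-based inclusive activity-window bounds,
        counted from the PAM-distal (5') end of the protospacer.
    spacer_length : protospacer length in nt.
    """

    name: str
    editor_class: EditorClass
    target_base: str
    converted_base: str
    pam_pattern: str
    window_start: int
    window_end: int
    spacer_length: int

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigError("editor entry: 'name' must be non-empty")
        if not isinstance(self.editor_class, EditorClass):
            raise ConfigError(
                f"editor {self.name!r}: 'class' must be one of "
                f"{[c.value for c in EditorClass]}"
            )
        expected = _CLASS_CHEMISTRY[self.editor_class]
        if (self.target_base, self.converted_base) != expected:
            raise ConfigError(
                f"editor {self.name!r}: class {self.editor_class.value} implies "
                f"{expected[0]}->{expected[1]}, got "
                f"{self.target_base}->{self.converted_base}"
            )
        if not is_iupac(self.pam_pattern):
            raise ConfigError(
                f"editor {self.name!r}: 'pam_pattern' must be a non-empty IUPAC "
                f"string, got {self.pam_pattern!r}"
            )
        if self.spacer_length < 1:
            raise ConfigError(f"editor {self.name!r}: 'spacer_length' must be >= 1")
        if not (1 <= self.window_start <= self.window_end <= self.spacer_length):
            raise ConfigError(
                f"editor {self.name!r}: require 1 <= window_start <= window_end "
                f"<= spacer_length, got window {self.window_start}-"
                f"{self.window_end}, spacer {self.spacer_length}"
            )

    @property
    def window(self) -> range:
        """Activity-window positions as an inclusive 1-based range."""
        return range(self.window_start, self.window_end + 1)


BE3 = BaseEditor("BE3", EditorClass.CBE, "C", "T", "NGG", 4, 8, 20)
ABE710 = BaseEditor("ABE7.10", EditorClass.ABE, "A", "G", "NGG", 4, 7, 20)

DEFAULT_EDITORS = (BE3, ABE710)

_ENTRY_KEYS = {"name", "class", "pam", "window", "spacer",
               "target_base", "converted_base"}


class EditorRegistry:
    """Case-insensitive name -> :class:`BaseEditor` mapping."""

    def __init__(self, editors: Iterable[BaseEditor] = ()):
        self._editors: dict[str, BaseEditor] = {}
        for ed in editors:
            self.add(ed)

    def add(self, editor: BaseEditor) -> None:
        self._editors[editor.name.lower()] = editor

    def get(self, name: str) -> BaseEditor:
        try:
            return self._editors[name.lower()]
        except KeyError:
            raise EditorLookupError(
                f"unknown editor {name!r}; available: {', '.join(self.names())}"
            ) from None

    def names(self) -> list[str]:
        return [ed.name for ed in self._editors.values()]

    def __iter__(self) -> Iterator[BaseEditor]:
        return iter(self._editors.values())

    def __len__(self) -> int:
        return len(self._editors)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EditorRegistry):
            return NotImplemented
        return self._editors == other._editors

    def to_config(self) -> str:
        """Serialize to YAML; ``load_editors`` on the result round-trips."""
        entries = []
        for ed in self:
            entries.append({
                "name": ed.name,
                "class": ed.editor_class.value,
                "pam": ed.pam_pattern,
                "window": [ed.window_start, ed.window_end],
                "spacer": ed.spacer_length,
            })
        return yaml.safe_dump({"editors": entries}, sort_keys=False)


def _parse_entry(entry: object) -> BaseEditor:
    if not isinstance(entry, dict):
        raise ConfigError(f"editor entry must be a mapping, got {type(entry).__name__}")
    unknown = set(entry) - _ENTRY_KEYS
    if unknown:
        raise ConfigError(
            f"editor entry {entry.get('name', '?')!r}: unknown field(s) "
            f"{sorted(unknown)}"
        )
    for field in ("name", "class", "pam", "window", "spacer"):
        if field not in entry:
            raise ConfigError(
                f"editor entry {entry.get('name', '?')!r}: missing field {field!r}"
            )
    try:
        cls = EditorClass(str(entry["class"]).upper())
    except ValueError:
        raise ConfigError(
            f"editor entry {entry['name']!r}: 'class' must be CBE or ABE, "
            f"got {entry['class']!r}"
        ) from None
    window = entry["window"]
    if not (isinstance(window, (list, tuple)) and len(window) == 2):
        raise ConfigError(
            f"editor entry {entry['name']!r}: 'window' must be [start, end]"
        )
    target, converted = _CLASS_CHEMISTRY[cls]
    target = str(entry.get("target_base", target)).upper()
    converted = str(entry.get("converted_base", converted)).upper()
    return BaseEditor(
        name=str(entry["name"]),
        editor_class=cls,
        target_base=target,
        converted_base=converted,
        pam_pattern=str(entry["pam"]).upper(),
        window_start=int(window[0]),
        window_end=int(window[1]),
        spacer_length=int(entry["spacer"]),
    )


def load_editors(config_source: Union[str, Path, None] = None) -> EditorRegistry:
    """Load an editor registry from YAML text or a file path.

    The shipped defaults (BE3, ABE7.10) are always present; config entries
    with the same (case-insensitive) name override them, other entries are
    added. An empty or absent config yields the defaults alone. Unknown
    keys in an entry are rejected.
    """
    text = ""
    if config_source is not None:
        if isinstance(config_source, Path):
            text = config_source.read_text()
        elif isinstance(config_source, str) and "\n" not in config_source and \
                config_source.strip() and Path(config_source).is_file():
            text = Path(config_source).read_text()
        else:
            text = str(config_source)
    try:
        doc = yaml.safe_load(io.StringIO(text))
    except yaml.YAMLError as exc:
        raise ConfigError(f"editor config is not valid YAML: {exc}") from exc

    registry = EditorRegistry(DEFAULT_EDITORS)
    if doc is None:
        return registry
    if not isinstance(doc, dict) or set(doc) - {"editors"}:
        raise ConfigError("editor config must be a mapping with a single "
                          "'editors' list")
    for entry in doc.get("editors") or []:
        registry.add(_parse_entry(entry))
    return registry


def get_editor(name: str, registry: EditorRegistry | None = None) -> BaseEditor:
    """Look up an editor by name (case-insensitive) in ``registry`` or defaults."""
    if registry is None:
        registry = EditorRegistry(DEFAULT_EDITORS)
    return registry.get(name)
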