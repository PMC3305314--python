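"""Loading and validation of the declarative class-signature registry.

Signatures are data, not code: the 14 LIM classes and their families ship
as a structured YAML file (templates, criteria subsets, spacing
constraints), so lineage variants or new classes need no code change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Mapping, Sequence

import yaml

__all__ = [
    "TemplateElement",
    "SpacingConstraint",
    "FamilySignature",
    "ClassSignature",
    "SignatureRegistry",
    "load_registry",
    "load_motif_regexes",
    "default_signatures_path",
]

CRITERIA = ("count", "groups", "order", "architecture")


class SignatureConfigError(ValueError):
    """Raised when a signature file references unknown names or is malformed."""


@dataclass(frozen=True)
class TemplateElement:
    kind: str  # lim | domain | motif
    name: str  # "LIM" for lim slots, model or motif name otherwise
    required: bool = True

    def __str__(self) -> str:
        flag = "" if self.required else "?"
        return f"{self.kind}:{self.name}{flag}"


@dataclass(frozen=True)
class SpacingConstraint:
    """Either a start-position constraint on one element or a gap constraint
    between two; element refs look like ``lim:2`` or ``domain:Nebulin:1``."""

    measure: str  # start | gap
    min: int
    max: int
    element: str | None = None  # for measure=start
    a: str | None = None  # for measure=gap
    b: str | None = None

    def describe(self) -> str:
        if self.measure == "start":
            return f"start({self.element}) in [{self.min},{self.max}]"
        return f"gap({self.a},{self.b}) in [{self.min},{self.max}]"


@dataclass
class FamilySignature:
    class_name: str
    name: str
    lim_count: tuple[int, int]
    template: list[TemplateElement]
    forbidden: list[TemplateElement] = field(default_factory=list)
    spacing: list[SpacingConstraint] = field(default_factory=list)

    @property
    def label(self) -> str:
        return f"{self.class_name}/{self.name}"


@dataclass
class ClassSignature:
    name: str
    required_criteria: frozenset[str]
    families: dict[str, FamilySignature]


@dataclass
class SignatureRegistry:
    classes: dict[str, ClassSignature]
    domain_widths: dict[str, int]
    motif_regexes: dict[str, str]

    @property
    def class_names(self) -> list[str]:
        return sorted(self.classes)

    def family(self, class_name: str, family_name: str) -> FamilySignature:
        return self.classes[class_name].families[family_name]

    def all_families(self) -> list[FamilySignature]:
        return [
            fam
            for cls in self.classes.values()
            for fam in cls.families.values()
        ]


def default_signatures_path() -> str:
    return str(resources.files("limclass.data") / "signatures.yaml")


def default_motifs_path() -> str:
    return str(resources.files("limclass.data") / "motifs.yaml")


def load_motif_regexes(path: str | None = None) -> dict[str, str]:
    with open(path or default_motifs_path()) as handle:
        data = yaml.safe_load(handle)
    motifs = data.get("motifs", {})
    if not isinstance(motifs, dict) or not motifs:
        raise SignatureConfigError("motif config must contain a 'motifs' map")
    return {str(k): str(v) for k, v in motifs.items()}


def _parse_element(raw: Any, where: str) -> TemplateElement:
    if raw == "lim":
        return TemplateElement("lim", "LIM", True)
    if isinstance(raw, Mapping):
        required = bool(raw.get("required", True))
        if "lim" in raw:
            return TemplateElement("lim", "LIM", required)
        if "domain" in raw:
            return TemplateElement("domain", str(raw["domain"]), required)
        if "motif" in raw:
            return TemplateElement("motif", str(raw["motif"]), required)
    raise SignatureConfigError(f"{where}: cannot parse template element {raw!r}")


def _parse_lim_count(raw: Any, where: str) -> tuple[int, int]:
    if isinstance(raw, int):
        return (raw, raw)
    if (
        isinstance(raw, (list, tuple))
        and len(raw) == 2
        and all(isinstance(v, int) for v in raw)
        and raw[0] <= raw[1]
    ):
        return (raw[0], raw[1])
    raise SignatureConfigError(f"{where}: bad lim_count {raw!r}")


def _parse_spacing(raw: Any, where: str) -> SpacingConstraint:
    if not isinstance(raw, Mapping) or "measure" not in raw:
        raise SignatureConfigError(f"{where}: bad spacing entry {raw!r}")
    measure = raw["measure"]
    lo, hi = int(raw["min"]), int(raw["max"])
    if lo > hi:
        raise SignatureConfigError(f"{where}: spacing min > max in {raw!r}")
    if measure == "start":
        if "element" not in raw:
            raise SignatureConfigError(f"{where}: start constraint needs 'element'")
        return SpacingConstraint("start", lo, hi, element=str(raw["element"]))
    if measure == "gap":
        if "a" not in raw or "b" not in raw:
            raise SignatureConfigError(f"{where}: gap constraint needs 'a' and 'b'")
        return SpacingConstraint("gap", lo, hi, a=str(raw["a"]), b=str(raw["b"]))
    raise SignatureConfigError(f"{where}: unknown measure {measure!r}")


def _ref_name(ref: str, where: str) -> tuple[str, str]:
    """Split an element ref like 'domain:Nebulin:1' into (kind, name)."""
    parts = ref.split(":")
    if parts[0] == "lim":
        return "lim", "LIM"
    if parts[0] in ("domain", "motif") and len(parts) >= 2:
        return parts[0], parts[1]
    raise SignatureConfigError(f"{where}: bad element reference {ref!r}")


def load_registry(
    signatures_path: str | None = None,
    motifs_path: str | None = None,
) -> SignatureRegistry:
    """Load and validate the signature registry.

    Template elements referencing motif names absent from the motif table or
    domain names absent from the domain list raise
    :class:`SignatureConfigError` at load time.
    """
    motif_regexes = load_motif_regexes(motifs_path)
    with open(signatures_path or default_signatures_path()) as handle:
        data = yaml.safe_load(handle)
    domain_widths = {
        str(k): int(v) for k, v in (data.get("domains") or {}).items()
    }
    raw_classes = data.get("classes")
    if not raw_classes:
        raise SignatureConfigError("signature config must contain 'classes'")

    classes: dict[str, ClassSignature] = {}
    for cname, spec in raw_classes.items():
        where = f"class {cname}"
        required = spec.get("required_criteria", [])
        bad = set(required) - set(CRITERIA)
        if bad:
            raise SignatureConfigError(f"{where}: unknown criteria {sorted(bad)}")
        families: dict[str, FamilySignature] = {}
        for fname, fspec in (spec.get("families") or {}).items():
            fwhere = f"{where}/{fname}"
            template = [
                _parse_element(e, fwhere) for e in fspec.get("template", [])
            ]
            forbidden = [
                _parse_element(e, fwhere) for e in fspec.get("forbidden", [])
            ]
            spacing = [
                _parse_spacing(s, fwhere) for s in fspec.get("spacing", [])
            ]
            for elem in template + forbidden:
                if elem.kind == "motif" and elem.name not in motif_regexes:
                    raise SignatureConfigError(
                        f"{fwhere}: unknown motif {elem.name!r}"
                    )
                if elem.kind == "domain" and elem.name not in domain_widths:
                    raise SignatureConfigError(
                        f"{fwhere}: unknown domain {elem.name!r}"
                    )
            for sc in spacing:
                refs = [r for r in (sc.element, sc.a, sc.b) if r]
                for ref in refs:
                    kind, name = _ref_name(ref, fwhere)
                    if kind == "motif" and name not in motif_regexes:
                        raise SignatureConfigError(
                            f"{fwhere}: spacing references unknown motif {name!r}"
                        )
                    if kind == "domain" and name not in domain_widths:
                        raise SignatureConfigError(
                            f"{fwhere}: spacing references unknown domain {name!r}"
                        )
            families[fname] = FamilySignature(
                class_name=cname,
                name=fname,
                lim_count=_parse_lim_count(fspec.get("lim_count"), fwhere),
                template=template,
                forbidden=forbidden,
                spacing=spacing,
            )
        if not families:
            raise SignatureConfigError(f"{where}: no families")
        classes[cname] = ClassSignature(
            name=cname,
            required_criteria=frozenset(required),
            families=families,
        )
    return SignatureRegistry(
        classes=classes,
        domain_widths=domain_widths,
        motif_regexes=motif_regexes,
    )
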