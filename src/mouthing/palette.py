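"""Coding palette: the controlled vocabulary behind every coded observation.

A coding palette declares three parallel channels — the object currently in
the child's mouth (``OBJECT``), the child's location (``LOCATION``), and the
ambient risk context (``CONTEXT``) — together with a strict risk-priority
order within each channel, a partition of the object states into exposure
groups (food, fomite, own hand/skin, other people's hand/skin, high-risk),
the subset of contexts flagged as high-risk, and the two sentinel object
states ``Nothing`` (no mouth contact) and ``NotInView`` (face/hands not
observable).

The default palette shipped with the package encodes 35 object states, 8
locations and 6 contexts.  Palettes are data, not code: studies in other
settings can ship their own config (the high-risk definitions in particular
are expected to be adapted to local conditions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

OBJECT = "OBJECT"
LOCATION = "LOCATION"
CONTEXT = "CONTEXT"
CHANNELS = (OBJECT, LOCATION, CONTEXT)

#: Recognised object exposure groups. ``sentinel`` is reserved for the two
#: non-contact states and never appears in the config's group mapping.
GROUPS = ("food", "fomite", "own_hand_skin", "other_hand_skin", "high_risk", "sentinel")


class PaletteError(ValueError):
    """A palette config violates the schema invariants."""


@dataclass(frozen=True)
class PaletteSchema:
    """Validated coding vocabulary.

    Parameters
    ----------
    states : mapping channel -> ordered state labels
        Order encodes descending risk priority (rank 0 = highest risk).
        The OBJECT list includes the two sentinels (conventionally last).
    object_groups : mapping OBJECT state -> group
        Partition of the non-sentinel object states into exposure groups.
    high_risk_contexts : frozenset of CONTEXT states
    outdoor_locations : frozenset of LOCATION states
        Everything else on the LOCATION channel is indoor.
    sentinels : mapping {"nothing": label, "not_in_view": label}
    eating_context : CONTEXT state representing eating activity
    """

    states: Mapping[str, tuple[str, ...]]
    object_groups: Mapping[str, str]
    high_risk_contexts: frozenset[str]
    outdoor_locations: frozenset[str]
    sentinels: Mapping[str, str]
    eating_context: str
    version: str = "1.0"
    _rank: Mapping[str, Mapping[str, int]] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        for ch in CHANNELS:
            if ch not in self.states or not self.states[ch]:
                raise PaletteError(f"channel {ch} missing or empty")
            labels = self.states[ch]
            dupes = {s for s in labels if list(labels).count(s) > 1}
            if dupes:
                raise PaletteError(f"duplicate state label(s) in {ch}: {sorted(dupes)}")
        for key in ("nothing", "not_in_view"):
            if key not in self.sentinels:
                raise PaletteError(f"missing sentinel declaration: {key}")
            if self.sentinels[key] not in self.states[OBJECT]:
                raise PaletteError(
                    f"sentinel {self.sentinels[key]!r} not an OBJECT state"
                )
        sent = set(self.sentinels.values())
        non_sentinel = [s for s in self.states[OBJECT] if s not in sent]
        mapped = set(self.object_groups)
        if mapped - set(non_sentinel):
            raise PaletteError(
                f"group mapping names unknown/sentinel object state(s): "
                f"{sorted(mapped - set(non_sentinel))}"
            )
        unmapped = set(non_sentinel) - mapped
        if unmapped:
            raise PaletteError(f"object state(s) without a group: {sorted(unmapped)}")
        bad_groups = set(self.object_groups.values()) - set(GROUPS)
        if bad_groups:
            raise PaletteError(f"unknown group label(s): {sorted(bad_groups)}")
        if "sentinel" in self.object_groups.values():
            raise PaletteError("'sentinel' group must not be assigned explicitly")
        extra = self.high_risk_contexts - set(self.states[CONTEXT])
        if extra:
            raise PaletteError(f"high-risk context(s) not on CONTEXT channel: {sorted(extra)}")
        extra = self.outdoor_locations - set(self.states[LOCATION])
        if extra:
            raise PaletteError(f"outdoor location(s) not on LOCATION channel: {sorted(extra)}")
        if self.eating_context not in self.states[CONTEXT]:
            raise PaletteError(f"eating context {self.eating_context!r} not a CONTEXT state")
        object.__setattr__(
            self,
            "_rank",
            {ch: {s: i for i, s in enumerate(self.states[ch])} for ch in CHANNELS},
        )

    # -- lookups ---------------------------------------------------------

    @property
    def nothing(self) -> str:
        return self.sentinels["nothing"]

    @property
    def not_in_view(self) -> str:
        return self.sentinels["not_in_view"]

    @property
    def sentinel_states(self) -> frozenset[str]:
        return frozenset(self.sentinels.values())

    def non_sentinel_objects(self) -> tuple[str, ...]:
        return tuple(s for s in self.states[OBJECT] if s not in self.sentinel_states)

    def indoor_locations(self) -> frozenset[str]:
        return frozenset(self.states[LOCATION]) - self.outdoor_locations

    def is_sentinel(self, state: str) -> bool:
        return state in self.sentinel_states

    def group_of(self, state: str) -> str:
        """Exposure group of an OBJECT state; sentinels map to ``sentinel``."""
        if state in self.sentinel_states:
            return "sentinel"
        try:
            return self.object_groups[state]
        except KeyError:
            raise PaletteError(f"unknown OBJECT state: {state!r}") from None

    def states_in_group(self, group: str) -> tuple[str, ...]:
        if group == "sentinel":
            return tuple(s for s in self.states[OBJECT] if s in self.sentinel_states)
        return tuple(s for s in self.states[OBJECT] if self.object_groups.get(s) == group)

    def groups(self) -> tuple[str, ...]:
        """Groups present in the mapping, in first-appearance (priority) order."""
        seen: list[str] = []
        for s in self.non_sentinel_objects():
            g = self.object_groups[s]
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    def rank(self, channel: str, state: str) -> int:
        try:
            return self._rank[channel][state]
        except KeyError:
            raise PaletteError(f"unknown state {state!r} on channel {channel}") from None

    def validate_state(self, channel: str, state: str) -> None:
        if channel not in self._rank:
            raise PaletteError(f"unknown channel: {channel!r}")
        if state not in self._rank[channel]:
            raise PaletteError(f"unknown state {state!r} on channel {channel}")


def resolve_priority(
    candidates: Iterable[str], schema: PaletteSchema, channel: str = OBJECT
) -> str:
    """Pick the highest-risk state among simultaneously observed candidates.

    Risk priority is the position in the configured state list (rank 0 is
    highest).  Deterministic, idempotent and order-independent.
    """
    cand = list(candidates)
    if not cand:
        raise PaletteError("resolve_priority: empty candidate set")
    return min(cand, key=lambda s: schema.rank(channel, s))


def _parse_mapping(doc: Mapping) -> PaletteSchema:
    try:
        channels = doc["channels"]
    except (KeyError, TypeError):
        raise PaletteError("config missing 'channels' section") from None
    groups_section = doc.get("object_groups", {})
    mapping: dict[str, str] = {}
    for group, states in groups_section.items():
        for s in states:
            if s in mapping:
                raise PaletteError(
                    f"object state {s!r} assigned to two groups: {mapping[s]} and {group}"
                )
            mapping[s] = group
    schema = PaletteSchema(
        states={ch: tuple(v) for ch, v in channels.items()},
        object_groups=mapping,
        high_risk_contexts=frozenset(doc.get("high_risk_contexts", ())),
        outdoor_locations=frozenset(doc.get("outdoor_locations", ())),
        sentinels=dict(doc.get("sentinels", {})),
        eating_context=doc.get("eating_context", "Eating"),
        version=str(doc.get("version", "1.0")),
    )
    expected = doc.get("expected_counts")
    if expected:
        sent = schema.sentinel_states
        for ch, want in expected.items():
            got = len([s for s in schema.states[ch] if s not in sent])
            if got != int(want):
                raise PaletteError(
                    f"channel {ch}: expected {want} non-sentinel states, found {got}"
                )
    return schema


def load_palette(source: str | Path) -> PaletteSchema:
    """Load and validate a palette from YAML/JSON text or a file path."""
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and source.endswith((".yaml", ".yml", ".json"))
    ):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise PaletteError("palette config must be a mapping document")
    return _parse_mapping(doc)


def default_palette() -> PaletteSchema:
    """The packaged default palette (35 objects / 8 locations / 6 contexts)."""
    text = resources.files("mouthing.data").joinpath("default_palette.yaml").read_text("utf-8")
    return load_palette(text)


def palette_to_json(schema: PaletteSchema) -> str:
    """JSON rendering of a schema (round-trips through ``load_palette``)."""
    groups: dict[str, list[str]] = {}
    for s, g in schema.object_groups.items():
        groups.setdefault(g, []).append(s)
    # preserve priority order inside each group
    for g in groups:
        groups[g].sort(key=lambda s: schema.rank(OBJECT, s))
    doc = {
        "version": schema.version,
        "channels": {ch: list(schema.states[ch]) for ch in CHANNELS},
        "sentinels": dict(schema.sentinels),
        "object_groups": groups,
        "high_risk_contexts": sorted(schema.high_risk_contexts),
        "eating_context": schema.eating_context,
        "outdoor_locations": sorted(schema.outdoor_locations),
    }
    return json.dumps(doc, indent=2)
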