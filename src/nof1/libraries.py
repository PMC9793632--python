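"""Preconfigured goal / intervention / measure templates.

The library ships four goals with linked intervention suggestions (willow
bark tea, arnica gel and a warming pad for back pain; magnesium, vitamin
B12 and massage for leg cramps; an omega-3 supplement, olive oil massage
and a cold patch for rheumatoid arthritis; gluten-free, fructose-free and
low-fiber diets for irritable bowel syndrome), plus general entries.  The
non-linked goals, interventions and measures are this package's own
examples.

Entries are *templates*: :func:`instantiate_template` hands out detached
copies with fresh ids, so edits never touch the shipped library.  The
content lives in a packaged JSON file (same dialect as trial components)
and can be extended without code changes.
"""

from __future__ import annotations

from importlib import resources
from typing import Optional, Union

from pydantic import BaseModel, ConfigDict, Field

from .trial_model import Goal, Intervention, Measure, new_id

__all__ = [
    "ComponentLibrary",
    "load_library",
    "suggestions_for_goal",
    "instantiate_template",
]

_DATA_PACKAGE = "nof1.data"
_LIBRARY_FILE = "library.json"

Component = Union[Goal, Intervention, Measure]


class ComponentLibrary(BaseModel):
    """The shipped template collection plus goal -> intervention links."""

    model_config = ConfigDict(extra="forbid")

    description: str = ""
    goals: list[Goal] = Field(default_factory=list)
    interventions: list[Intervention] = Field(default_factory=list)
    measures: list[Measure] = Field(default_factory=list)
    links: dict[str, list[str]] = Field(default_factory=dict)

    def intervention_by_name(self, name: str) -> Optional[Intervention]:
        for iv in self.interventions:
            if iv.name.casefold() == name.casefold():
                return iv
        return None


_cached: Optional[ComponentLibrary] = None


def load_library() -> ComponentLibrary:
    """Load the packaged library (cached; treat the result as read-only)."""
    global _cached
    if _cached is None:
        text = resources.files(_DATA_PACKAGE).joinpath(_LIBRARY_FILE).read_text("utf-8")
        _cached = ComponentLibrary.model_validate_json(text)
    return _cached


def suggestions_for_goal(goal_name: str,
                         library: Optional[ComponentLibrary] = None) -> list[Intervention]:
    """Intervention templates for a goal: linked suggestions first.

    The interventions linked to the (case-insensitively matched) goal lead
    the list in their configured order, followed by the remaining general
    library; an unknown goal simply yields the general library.
    """
    lib = library or load_library()
    linked_names = []
    for name, names in lib.links.items():
        if name.casefold() == goal_name.casefold():
            linked_names = names
            break
    linked = [iv for n in linked_names
              if (iv := lib.intervention_by_name(n)) is not None]
    linked_ids = {iv.id for iv in linked}
    rest = [iv for iv in lib.interventions if iv.id not in linked_ids]
    return linked + rest


def instantiate_template(template: Component) -> Component:
    """Deep-copy a template into an independently editable component.

    Interventions and measures get a fresh id; goals carry no id.
    """
    copy = template.model_copy(deep=True)
    if hasattr(copy, "id"):
        copy.id = new_id()
    return copy
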