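"""Reading, writing and linting workflow definition files.

The on-disk format is a deliberately small subset of XPDL 2.x — the element
skeleton ``Package → WorkflowProcesses → WorkflowProcess →
{Activities/Activity, Transitions/Transition}`` — with all record-system
semantics carried in ``ExtendedAttribute`` elements:

* ``FLUX_FIELD`` (one per attribute, on an Activity): a semicolon-separated
  ``KEY=value`` record with keys ``NAME, KIND, REQUIRED, MIN, MAX, CHOICES,
  REGISTRY, FORMULA, COLUMNS, EXAMPLE, HINT``;
* ``FLUX_REGISTRY`` (package level): ``NAME, EXTENSIBLE, ENTRIES``;
* ``FLUX_SUGGEST`` (package level): ``ID, SOURCE, CONDITION, SUGGEST``.

Graphics, layout, pools, lanes, deadlines and sub-flows are ignored or
rejected; an editor may write them, the engine never reads them.

The linter and the parser share one analysis pass, which yields the
soundness guarantee the engine relies on: a document parses if and only if
linting finds zero error-severity issues, so ``lint`` is a complete preflight
for workflow authors editing protocols by hand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from lxml import etree

from .errors import FormulaSyntaxError, WorkflowParseError
from .formula import Formula, parse_formula
from .model import (
    KINDS,
    ActivityDef,
    AttributeDef,
    RegistryDef,
    SuggestionRule,
    Transition,
    WorkflowDefinition,
)

__all__ = [
    "LintIssue",
    "lint_workflow",
    "parse_workflow",
    "serialize_workflow",
    "parse_workflow_file",
    "lint_workflow_file",
    "XPDL_NS",
]

XPDL_NS = "http://www.wfmc.org/2008/XPDL2.1"

_FIELD_KEYS = (
    "NAME",
    "KIND",
    "REQUIRED",
    "MIN",
    "MAX",
    "CHOICES",
    "REGISTRY",
    "FORMULA",
    "COLUMNS",
    "EXAMPLE",
    "HINT",
)
_REGISTRY_KEYS = ("NAME", "EXTENSIBLE", "ENTRIES")
_SUGGEST_KEYS = ("ID", "SOURCE", "CONDITION", "SUGGEST")


@dataclass(frozen=True)
class LintIssue:
    """One linter finding. Error-severity issues make a document unloadable."""

    severity: str  # "error" | "warning"
    code: str
    location: str
    message: str
    line: int | None = None

    def __str__(self) -> str:  # the CLI prints issues in this form
        return f"{self.severity.upper()} {self.code} {self.location} {self.message}"


def _local(el) -> str:
    tag = el.tag
    if isinstance(tag, str) and tag.startswith("{"):
        return tag.split("}", 1)[1]
    return tag if isinstance(tag, str) else ""


def _children(el, name: str):
    return [c for c in el if isinstance(c.tag, str) and _local(c) == name]


def _first(el, *path):
    current = el
    for name in path:
        found = _children(current, name)
        if not found:
            return None
        current = found[0]
    return current


def _ext_attributes(el, name: str):
    """ExtendedAttribute children of an element's ExtendedAttributes block."""
    block = _first(el, "ExtendedAttributes")
    if block is None:
        return []
    return [
        ea
        for ea in _children(block, "ExtendedAttribute")
        if ea.get("Name") == name
    ]


def _parse_record(text: str):
    """Split ``K=v;K=v`` into an ordered list of (key, value) pairs.

    Returns (pairs, bad_segments); segments without ``=`` are reported, empty
    segments are ignored. Values keep internal whitespace; keys are taken
    verbatim (the vocabulary is upper-case).
    """
    pairs: list[tuple[str, str]] = []
    bad: list[str] = []
    for segment in text.split(";"):
        segment = segment.strip()
        if not segment:
            continue
        if "=" not in segment:
            bad.append(segment)
            continue
        key, value = segment.split("=", 1)
        pairs.append((key.strip(), value.strip()))
    return pairs, bad


class _Analysis:
    """One shared pass producing both the lint report and the model."""

    def __init__(self, source: str | bytes):
        self.issues: list[LintIssue] = []
        self.source = source

    def error(self, code: str, location: str, message: str, line=None) -> None:
        self.issues.append(LintIssue("error", code, location, message, line))

    def warn(self, code: str, location: str, message: str, line=None) -> None:
        self.issues.append(LintIssue("warning", code, location, message, line))

    @property
    def has_errors(self) -> bool:
        return any(i.severity == "error" for i in self.issues)

    # -- field record decoding -------------------------------------------

    def _decode_field(self, record: str, location: str, line) -> AttributeDef | None:
        pairs, bad = _parse_record(record)
        for segment in bad:
            self.error(
                "bad-field-record", location, f"segment {segment!r} is not KEY=value", line
            )
        keys = [k for k, _ in pairs]
        for key in keys:
            if key not in _FIELD_KEYS:
                self.warn(
                    "unknown-field-key", location, f"unknown key {key!r} ignored", line
                )
        if len(set(keys)) != len(keys):
            self.error("bad-field-record", location, "duplicate keys in record", line)
            return None
        data = dict(pairs)
        name = data.get("NAME", "")
        if not name:
            self.error("bad-field-record", location, "missing NAME", line)
            return None
        location = f"{location}/{name}"
        kind = data.get("KIND", "")
        if kind not in KINDS:
            self.error(
                "unsupported-kind", location, f"unknown attribute kind {kind!r}", line
            )
            return None

        required = False
        if "REQUIRED" in data:
            token = data["REQUIRED"].lower()
            if token not in ("true", "false"):
                self.error(
                    "bad-field-record",
                    location,
                    f"REQUIRED must be true or false, got {data['REQUIRED']!r}",
                    line,
                )
                return None
            required = token == "true"

        minimum = maximum = None
        for key in ("MIN", "MAX"):
            if key in data:
                if kind not in ("integer", "real"):
                    self.warn(
                        "irrelevant-key",
                        location,
                        f"{key} is ignored for kind {kind!r}",
                        line,
                    )
                    continue
                try:
                    bound = float(data[key])
                except ValueError:
                    self.error(
                        "bad-field-record", location, f"{key}={data[key]!r} is not numeric", line
                    )
                    return None
                if key == "MIN":
                    minimum = bound
                else:
                    maximum = bound
        if minimum is not None and maximum is not None and minimum > maximum:
            self.error("bad-field-record", location, "MIN exceeds MAX", line)
            return None

        choices: tuple[str, ...] = ()
        if kind == "choice":
            raw = data.get("CHOICES", "")
            choices = tuple(c.strip() for c in raw.split(",") if c.strip())
            if not choices:
                self.error("missing-choices", location, "choice kind needs CHOICES", line)
                return None
            if len(set(choices)) != len(choices):
                self.error("bad-field-record", location, "duplicate choices", line)
                return None
        elif "CHOICES" in data:
            self.warn("irrelevant-key", location, "CHOICES ignored for this kind", line)

        registry = None
        if kind == "register":
            registry = data.get("REGISTRY", "") or None
            if registry is None:
                self.error("missing-registry", location, "register kind needs REGISTRY", line)
                return None
        elif "REGISTRY" in data:
            self.warn("irrelevant-key", location, "REGISTRY ignored for this kind", line)

        columns: tuple[tuple[str, str], ...] = ()
        if kind == "table":
            raw = data.get("COLUMNS", "")
            parsed: list[tuple[str, str]] = []
            for part in raw.split(","):
                part = part.strip()
                if not part:
                    continue
                if ":" not in part:
                    self.error(
                        "bad-field-record",
                        location,
                        f"column {part!r} is not name:kind",
                        line,
                    )
                    return None
                col_name, col_kind = (p.strip() for p in part.split(":", 1))
                # Columns carry no nested constraint vocabulary, so only the
                # self-describing scalar kinds are allowed in tables.
                if col_kind not in ("integer", "real", "text", "date"):
                    self.error(
                        "bad-table-column",
                        location,
                        f"column {col_name!r} has non-scalar kind {col_kind!r}",
                        line,
                    )
                    return None
                parsed.append((col_name, col_kind))
            if not parsed:
                self.error("missing-columns", location, "table kind needs COLUMNS", line)
                return None
            if len({c for c, _ in parsed}) != len(parsed):
                self.error("bad-field-record", location, "duplicate column names", line)
                return None
            columns = tuple(parsed)
        elif "COLUMNS" in data:
            self.warn("irrelevant-key", location, "COLUMNS ignored for this kind", line)

        formula: Formula | None = None
        if kind == "computed":
            text = data.get("FORMULA", "")
            if not text:
                self.error("missing-formula", location, "computed kind needs FORMULA", line)
                return None
            try:
                formula = parse_formula(text)
            except FormulaSyntaxError as exc:
                self.error("bad-formula", location, str(exc), line)
                return None
        elif "FORMULA" in data:
            self.warn("irrelevant-key", location, "FORMULA ignored for this kind", line)

        return AttributeDef(
            name=name,
            kind=kind,
            required=required,
            min=minimum,
            max=maximum,
            choices=choices,
            registry=registry,
            columns=columns,
            formula=formula,
            example=data.get("EXAMPLE") or None,
            hint=data.get("HINT") or None,
        )

    def _decode_registry(self, record: str, location: str, line) -> RegistryDef | None:
        pairs, bad = _parse_record(record)
        for segment in bad:
            self.error(
                "bad-registry-record", location, f"segment {segment!r} is not KEY=value", line
            )
        data = dict(pairs)
        for key in data:
            if key not in _REGISTRY_KEYS:
                self.warn("unknown-field-key", location, f"unknown key {key!r} ignored", line)
        name = data.get("NAME", "")
        if not name:
            self.error("bad-registry-record", location, "missing NAME", line)
            return None
        token = data.get("EXTENSIBLE", "false").lower()
        if token not in ("true", "false"):
            self.error(
                "bad-registry-record", f"{location}/{name}", "EXTENSIBLE must be true or false", line
            )
            return None
        entries = tuple(
            e.strip() for e in data.get("ENTRIES", "").split(",") if e.strip()
        )
        if len(set(entries)) != len(entries):
            self.error(
                "bad-registry-record", f"{location}/{name}", "duplicate registry entries", line
            )
            return None
        return RegistryDef(registry_name=name, entries=entries, extensible=token == "true")

    def _decode_suggest(self, record: str, location: str, line) -> SuggestionRule | None:
        pairs, bad = _parse_record(record)
        for segment in bad:
            self.error(
                "bad-suggest-record", location, f"segment {segment!r} is not KEY=value", line
            )
        data = dict(pairs)
        for key in data:
            if key not in _SUGGEST_KEYS:
                self.warn("unknown-field-key", location, f"unknown key {key!r} ignored", line)
        rule_id = data.get("ID", "")
        source = data.get("SOURCE", "")
        condition_text = data.get("CONDITION", "")
        if not rule_id or not source or not condition_text:
            self.error(
                "bad-suggest-record", location, "rule needs ID, SOURCE and CONDITION", line
            )
            return None
        try:
            condition = parse_formula(condition_text)
        except FormulaSyntaxError as exc:
            self.error("bad-formula", f"{location}/{rule_id}", str(exc), line)
            return None
        suggested = tuple(
            s.strip() for s in data.get("SUGGEST", "").split(",") if s.strip()
        )
        return SuggestionRule(
            rule_id=rule_id,
            source_activity=source,
            condition=condition,
            suggested_activities=suggested,
        )

    # -- main pass --------------------------------------------------------

    def run(self) -> WorkflowDefinition | None:
        source = self.source
        if isinstance(source, str):
            source = source.encode("utf-8")
        try:
            root = etree.fromstring(source)
        except etree.XMLSyntaxError as exc:
            line = exc.lineno if hasattr(exc, "lineno") else None
            self.error("malformed-xml", "document", str(exc), line)
            return None

        if _local(root) != "Package":
            self.error(
                "not-xpdl", "document", f"root element is {_local(root)!r}, expected Package"
            )
            return None

        process = _first(root, "WorkflowProcesses", "WorkflowProcess")
        if process is None:
            self.error("missing-process", "document", "no WorkflowProcess element")
            return None

        workflow_id = process.get("Id") or root.get("Id") or ""
        if not workflow_id:
            self.error("missing-id", "process", "WorkflowProcess has no Id")
        wf_name = process.get("Name") or root.get("Name") or workflow_id
        version_el = _first(process, "RedefinableHeader", "Version")
        version = (version_el.text or "").strip() if version_el is not None else ""
        version = version or "1.0"

        # registries and suggestion rules (package level)
        registries: dict[str, RegistryDef] = {}
        for ea in _ext_attributes(root, "FLUX_REGISTRY"):
            reg = self._decode_registry(ea.get("Value", ""), "registry", ea.sourceline)
            if reg is None:
                continue
            if reg.registry_name in registries:
                self.error(
                    "duplicate-registry",
                    f"registry/{reg.registry_name}",
                    "registry declared twice",
                    ea.sourceline,
                )
                continue
            registries[reg.registry_name] = reg

        rules: list[SuggestionRule] = []
        for ea in _ext_attributes(root, "FLUX_SUGGEST"):
            rule = self._decode_suggest(ea.get("Value", ""), "suggest", ea.sourceline)
            if rule is not None:
                rules.append(rule)
        rule_ids = [r.rule_id for r in rules]
        for rid in sorted({r for r in rule_ids if rule_ids.count(r) > 1}):
            self.error("duplicate-rule", f"suggest/{rid}", "rule id declared twice")

        # activities, in document order
        activities: list[ActivityDef] = []
        seen_ids: set[str] = set()
        activities_el = _first(process, "Activities")
        for act_el in _children(activities_el, "Activity") if activities_el is not None else []:
            act_id = act_el.get("Id") or ""
            act_name = act_el.get("Name") or ""
            location = f"activity/{act_id or '?'}"
            if not act_id:
                self.error("missing-id", location, "Activity has no Id", act_el.sourceline)
                continue
            if not act_name:
                self.error(
                    "missing-name", location, "Activity has no Name", act_el.sourceline
                )
            if act_id in seen_ids:
                self.error(
                    "duplicate-activity-id", location, "activity id declared twice",
                    act_el.sourceline,
                )
                continue
            seen_ids.add(act_id)
            attributes: list[AttributeDef] = []
            for ea in _ext_attributes(act_el, "FLUX_FIELD"):
                attr = self._decode_field(ea.get("Value", ""), location, ea.sourceline)
                if attr is not None:
                    attributes.append(attr)
            names = [a.name for a in attributes]
            for name in sorted({n for n in names if names.count(n) > 1}):
                self.error(
                    "duplicate-attribute",
                    f"{location}/{name}",
                    "attribute name declared twice in activity",
                )
            activities.append(
                ActivityDef(activity_id=act_id, name=act_name, attributes=tuple(attributes))
            )

        # transitions
        transitions: list[Transition] = []
        seen_pairs: set[tuple[str, str]] = set()
        transitions_el = _first(process, "Transitions")
        for tr_el in _children(transitions_el, "Transition") if transitions_el is not None else []:
            src = tr_el.get("From") or ""
            dst = tr_el.get("To") or ""
            location = f"transition/{src or '?'}->{dst or '?'}"
            if not src or not dst:
                self.error(
                    "bad-transition", location, "Transition needs From and To", tr_el.sourceline
                )
                continue
            if src == dst:
                self.error(
                    "self-loop-transition", location, "transition loops to itself",
                    tr_el.sourceline,
                )
                continue
            if (src, dst) in seen_pairs:
                self.error(
                    "duplicate-transition", location, "transition declared twice",
                    tr_el.sourceline,
                )
                continue
            seen_pairs.add((src, dst))
            transitions.append(Transition(from_activity=src, to_activity=dst))

        self._check_graph(activities, transitions, registries, rules)
        if self.has_errors:
            return None
        return WorkflowDefinition(
            workflow_id=workflow_id,
            name=wf_name,
            version=version,
            activities=tuple(activities),
            transitions=tuple(transitions),
            registries=registries,
            suggestion_rules=tuple(rules),
        )

    def _check_graph(self, activities, transitions, registries, rules) -> None:
        ids = {a.activity_id for a in activities}
        by_id = {a.activity_id: a for a in activities}

        for tr in transitions:
            for endpoint in (tr.from_activity, tr.to_activity):
                if endpoint not in ids:
                    self.error(
                        "unknown-transition-endpoint",
                        f"transition/{tr.from_activity}->{tr.to_activity}",
                        f"activity {endpoint!r} does not exist",
                    )

        targets = {t.to_activity for t in transitions if t.to_activity in ids}
        starts = [a for a in by_id if a not in targets]
        if activities and not starts:
            self.error(
                "no-start-activity",
                "process",
                "every activity has an incoming transition; no start exists",
            )

        # forward reachability for the unreachable-activity warning
        reachable = set(starts)
        frontier = list(starts)
        successors: dict[str, set[str]] = {}
        predecessors: dict[str, set[str]] = {}
        for tr in transitions:
            successors.setdefault(tr.from_activity, set()).add(tr.to_activity)
            predecessors.setdefault(tr.to_activity, set()).add(tr.from_activity)
        while frontier:
            current = frontier.pop()
            for nxt in successors.get(current, ()):
                if nxt in ids and nxt not in reachable:
                    reachable.add(nxt)
                    frontier.append(nxt)
        for act in activities:
            if act.activity_id not in reachable:
                self.warn(
                    "unreachable-activity",
                    f"activity/{act.activity_id}",
                    "activity cannot be reached from any start activity",
                )
            if len(predecessors.get(act.activity_id, ())) > 1:
                self.warn(
                    "or-join",
                    f"activity/{act.activity_id}",
                    "multiple incoming transitions: becomes available when ANY predecessor has run",
                )

        def ancestor_ids(start: str) -> set[str]:
            seen: set[str] = set()
            stack = [start]
            while stack:
                for pred in predecessors.get(stack.pop(), ()):
                    if pred not in seen:
                        seen.add(pred)
                        stack.append(pred)
            seen.discard(start)
            return seen

        for act in activities:
            own = set(act.attribute_names)
            ancestor_names: set[str] = set()
            for anc in ancestor_ids(act.activity_id):
                if anc in by_id:
                    ancestor_names.update(by_id[anc].attribute_names)
            for attr in act.attributes:
                location = f"activity/{act.activity_id}/{attr.name}"
                if attr.kind == "register" and attr.registry not in registries:
                    self.error(
                        "unknown-registry",
                        location,
                        f"registry {attr.registry!r} is not declared",
                    )
                if attr.kind == "computed" and attr.formula is not None:
                    for ref in sorted(attr.formula.referenced_names):
                        if ref == attr.name or (
                            ref not in own and ref not in ancestor_names
                        ):
                            self.error(
                                "unknown-formula-symbol",
                                location,
                                f"formula references {ref!r}, which is not an attribute "
                                "of this activity or an ancestor",
                            )
                        elif ref in own and ref in ancestor_names:
                            self.warn(
                                "attribute-shadowing",
                                location,
                                f"{ref!r} exists here and in an ancestor; the local value wins",
                            )

        for rule in rules:
            location = f"suggest/{rule.rule_id}"
            if rule.source_activity not in ids:
                self.error(
                    "unknown-activity-in-rule",
                    location,
                    f"source activity {rule.source_activity!r} does not exist",
                )
            else:
                source_names = set(by_id[rule.source_activity].attribute_names)
                for ref in sorted(rule.condition.referenced_names):
                    if ref not in source_names:
                        self.error(
                            "rule-symbol-outside-source",
                            location,
                            f"condition references {ref!r}, not an attribute of "
                            f"{rule.source_activity!r}",
                        )
            for suggested in rule.suggested_activities:
                if suggested not in ids:
                    self.error(
                        "unknown-activity-in-rule",
                        location,
                        f"suggested activity {suggested!r} does not exist",
                    )


def lint_workflow(source: str | bytes) -> list[LintIssue]:
    """Lint a workflow document; accepts broken input, returns all findings."""
    analysis = _Analysis(source)
    analysis.run()
    return analysis.issues


def parse_workflow(source: str | bytes) -> WorkflowDefinition:
    """Parse a workflow document or raise :class:`WorkflowParseError`.

    Exactly the documents with zero error-severity lint issues parse.
    """
    analysis = _Analysis(source)
    wf = analysis.run()
    if wf is None:
        raise WorkflowParseError(analysis.issues)
    return wf


def parse_workflow_file(path) -> WorkflowDefinition:
    return parse_workflow(Path(path).read_bytes())


def lint_workflow_file(path) -> list[LintIssue]:
    return lint_workflow(Path(path).read_bytes())


# -- serialization ---------------------------------------------------------


def _num_to_str(value: float) -> str:
    if value == int(value):
        return str(int(value))
    return repr(value)


def _record(pairs: list[tuple[str, str]]) -> str:
    for key, value in pairs:
        if ";" in value:
            raise ValueError(
                f"value for {key} contains ';', which the record encoding reserves"
            )
    return ";".join(f"{k}={v}" for k, v in pairs)


def _field_record(attr: AttributeDef) -> str:
    pairs: list[tuple[str, str]] = [("NAME", attr.name), ("KIND", attr.kind)]
    if attr.required:
        pairs.append(("REQUIRED", "true"))
    if attr.min is not None:
        pairs.append(("MIN", _num_to_str(attr.min)))
    if attr.max is not None:
        pairs.append(("MAX", _num_to_str(attr.max)))
    if attr.choices:
        for choice in attr.choices:
            if "," in choice:
                raise ValueError(f"choice {choice!r} contains ','")
        pairs.append(("CHOICES", ",".join(attr.choices)))
    if attr.registry:
        pairs.append(("REGISTRY", attr.registry))
    if attr.columns:
        pairs.append(("COLUMNS", ",".join(f"{n}:{k}" for n, k in attr.columns)))
    if attr.formula is not None:
        pairs.append(("FORMULA", attr.formula.expression))
    if attr.example:
        pairs.append(("EXAMPLE", attr.example))
    if attr.hint:
        pairs.append(("HINT", attr.hint))
    return _record(pairs)


def serialize_workflow(wf: WorkflowDefinition) -> str:
    """Serialize to XPDL-subset XML; output re-parses to an equal model."""
    nsmap = {None: XPDL_NS}

    def q(tag: str) -> str:
        return f"{{{XPDL_NS}}}{tag}"

    root = etree.Element(q("Package"), nsmap=nsmap)
    root.set("Id", wf.workflow_id)
    root.set("Name", wf.name)
    header = etree.SubElement(root, q("PackageHeader"))
    etree.SubElement(header, q("XPDLVersion")).text = "2.1"
    etree.SubElement(header, q("Vendor")).text = "fluxcase"

    if wf.registries or wf.suggestion_rules:
        block = etree.SubElement(root, q("ExtendedAttributes"))
        for reg in wf.registries.values():
            for entry in reg.entries:
                if "," in entry:
                    raise ValueError(f"registry entry {entry!r} contains ','")
            ea = etree.SubElement(block, q("ExtendedAttribute"))
            ea.set("Name", "FLUX_REGISTRY")
            ea.set(
                "Value",
                _record(
                    [
                        ("NAME", reg.registry_name),
                        ("EXTENSIBLE", "true" if reg.extensible else "false"),
                        ("ENTRIES", ",".join(reg.entries)),
                    ]
                ),
            )
        for rule in wf.suggestion_rules:
            ea = etree.SubElement(block, q("ExtendedAttribute"))
            ea.set("Name", "FLUX_SUGGEST")
            ea.set(
                "Value",
                _record(
                    [
                        ("ID", rule.rule_id),
                        ("SOURCE", rule.source_activity),
                        ("CONDITION", rule.condition.expression),
                        ("SUGGEST", ",".join(rule.suggested_activities)),
                    ]
                ),
            )

    processes = etree.SubElement(root, q("WorkflowProcesses"))
    process = etree.SubElement(processes, q("WorkflowProcess"))
    process.set("Id", wf.workflow_id)
    process.set("Name", wf.name)
    redef = etree.SubElement(process, q("RedefinableHeader"))
    etree.SubElement(redef, q("Version")).text = wf.version

    activities_el = etree.SubElement(process, q("Activities"))
    for act in wf.activities:
        act_el = etree.SubElement(activities_el, q("Activity"))
        act_el.set("Id", act.activity_id)
        act_el.set("Name", act.name)
        if act.attributes:
            block = etree.SubElement(act_el, q("ExtendedAttributes"))
            for attr in act.attributes:
                ea = etree.SubElement(block, q("ExtendedAttribute"))
                ea.set("Name", "FLUX_FIELD")
                ea.set("Value", _field_record(attr))

    transitions_el = etree.SubElement(process, q("Transitions"))
    for index, tr in enumerate(wf.transitions, start=1):
        tr_el = etree.SubElement(transitions_el, q("Transition"))
        tr_el.set("Id", f"t{index}")
        tr_el.set("From", tr.from_activity)
        tr_el.set("To", tr.to_activity)

    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")
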