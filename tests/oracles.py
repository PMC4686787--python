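"""Independent oracles the test suites check the implementation against.

These deliberately recompute results from first principles — raw id lists,
edge lists, brute-force counting — without going through the package's own
model helpers, so an implementation bug cannot hide in both places.
"""

from __future__ import annotations

import datetime


def state_oracle(activity_ids, edges, executed):
    """Recompute every activity's state from the raw edge list.

    executed: set of executed ids. An activity is executed if in the set,
    available if not executed and (it has no incoming edge, or some
    predecessor is executed), locked otherwise.
    """
    states = {}
    for act in activity_ids:
        if act in executed:
            states[act] = "executed"
            continue
        preds = [f for (f, t) in edges if t == act]
        if not preds or any(p in executed for p in preds):
            states[act] = "available"
        else:
            states[act] = "locked"
    return states


def _add_years(day: datetime.date, years: int) -> datetime.date:
    """Anniversary of ``day`` after ``years``; Feb 29 completes on Mar 1."""
    try:
        return day.replace(year=day.year + years)
    except ValueError:
        return datetime.date(day.year + years, 3, 1)


def years_between_oracle(later: datetime.date, earlier: datetime.date) -> int:
    """Count whole anniversaries by brute-force incrementing."""
    if later < earlier:
        return -years_between_oracle(earlier, later)
    count = 0
    while _add_years(earlier, count + 1) <= later:
        count += 1
    return count


def read_arff(text: str):
    """A minimal independent ARFF reader: (relation, attributes, data rows).

    attributes: list of (name, type-spec) where a nominal spec is a list of
    values. Handles single-quoted tokens with backslash escapes, ``?``
    missing markers and comment lines.
    """
    relation = None
    attributes = []
    data = []
    in_data = False

    def split_csv(line):
        out, cur, i, quoted = [], "", 0, False
        while i < len(line):
            c = line[i]
            if quoted:
                if c == "\\" and i + 1 < len(line):
                    cur += line[i + 1]
                    i += 2
                    continue
                if c == "'":
                    quoted = False
                else:
                    cur += c
            elif c == "'":
                quoted = True
            elif c == ",":
                out.append(cur)
                cur = ""
            else:
                cur += c
            i += 1
        out.append(cur)
        return out

    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("%"):
            continue
        if in_data:
            data.append([c.strip() for c in split_csv(line)])
            continue
        upper = line.upper()
        if upper.startswith("@RELATION"):
            relation = split_csv(line.split(None, 1)[1].strip())[0]
        elif upper.startswith("@ATTRIBUTE"):
            rest = line.split(None, 1)[1].strip()
            if rest.startswith("'"):
                end = 1
                while end < len(rest):
                    if rest[end] == "\\":
                        end += 2
                        continue
                    if rest[end] == "'":
                        break
                    end += 1
                name = split_csv(rest[: end + 1])[0]
                spec = rest[end + 1 :].strip()
            else:
                name, spec = rest.split(None, 1)
            if spec.startswith("{"):
                spec = [v.strip() for v in split_csv(spec.strip("{}"))]
                spec = [v for v in spec]
            attributes.append((name, spec))
        elif upper.startswith("@DATA"):
            in_data = True
    return relation, attributes, data
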