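"""Batch import of values and export to analysis-ready tables.

Feeds a small CSV through the batch path (the same route instrument output
takes), then renders the store as csv-long, csv-wide and ARFF, and prints a
per-case report.
"""

from fluxcase import batch, export
from fluxcase.fixtures import load_fixture
from fluxcase.store import Permission, Store, TickClock, User

wf = load_fixture("pcm")
store = Store(clock=TickClock())
store.add_workflow(wf)
store.add_user(User("lab", "Lab upload", "physician"))
store.grant_permission(
    Permission("physician", "*", "*", frozenset({"read", "write"}))
)

values_csv = """case_id,activity,attribute,row_index,column,value
1,identification,same_number,0,,1234
1,identification,name,0,,Maria Souza
1,first_consultation,consultation_date,0,,2014-03-02
1,first_consultation,condition_01,0,,yes
1,first_consultation,condition_02,0,,no
2,identification,same_number,0,,1235
2,identification,name,0,,Joao Lima
"""
summary = batch.batch_execute(values_csv, wf, store, "lab")
print(f"batch: {summary.n_executed} groups executed,"
      f" {sum(1 for g in summary.groups if not g.ok)} failed")
# Each (case, activity) group is one validated submission; a bad group never
# blocks the others.

long_text = export.render_export(store, wf, "csv-long")
print("csv-long data rows:", long_text.count("\n") - 1)
arff = export.render_export(store, wf, "arff")
print("ARFF declares", sum(1 for l in arff.splitlines()
                           if l.startswith("@ATTRIBUTE")), "attributes")
print()
print(export.case_report(store, wf, 1))
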