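"""Builders for the three packaged disease protocols.

These construct the workflow definitions from which the packaged ``.xpdl``
documents are generated (``python -m fluxcase.fixtures.regenerate``). The
published structural facts are: the neuromyelitis-optica (NMO) protocol has
16 activities including an Identification step with an auto-generated
patient number and a flexible Family History table; the
paracoccidioidomycosis (PCM) protocol identifies patients by their hospital
SAME number and batteries of 35 yes/no medical conditions and 29 yes/no
present/previous diseases in the First Consultation; the
adrenoleukodystrophy (ALD) protocol has 9 activities with extensible
treatment and symptom registries (defaults include Fatigue and Leg Pain)
and result-driven suggestions.

Activity names beyond the published ones, and the individual
condition/disease labels of the PCM batteries, are *reconstructions and
numbered stand-ins* — the structure is faithful, the medical content is
deliberately not invented (see the fixture file comments).
"""

from __future__ import annotations

from ..formula import parse_formula
from ..model import (
    ActivityDef,
    AttributeDef,
    RegistryDef,
    SuggestionRule,
    Transition,
    WorkflowDefinition,
)

__all__ = ["build_nmo", "build_pcm", "build_ald", "BUILDERS"]

_YES_NO = ("yes", "no")


def _yes_no(name: str) -> AttributeDef:
    return AttributeDef(name=name, kind="choice", choices=_YES_NO)


def build_nmo() -> WorkflowDefinition:
    """Neuromyelitis optica: 16 activities from identification to follow-up."""
    activities = (
        ActivityDef(
            "identification",
            "Identification",
            (
                AttributeDef("name", "text", required=True, example="Maria Souza",
                             hint="Full patient name"),
                AttributeDef("birth_date", "date", required=True, example="1980-06-01"),
                AttributeDef("education_level", "choice",
                             choices=("none", "primary", "secondary", "higher")),
                AttributeDef("city", "text"),
                AttributeDef("state", "text"),
                AttributeDef("country", "text"),
                AttributeDef("date_of_first_evaluation", "date", required=True,
                             hint="Reference date for all diagnostic intervals"),
                AttributeDef(
                    "age_at_first_evaluation", "computed",
                    formula=parse_formula(
                        "years_between(date_of_first_evaluation, birth_date)"
                    ),
                ),
            ),
        ),
        ActivityDef(
            "first_symptoms",
            "First Symptoms",
            (
                AttributeDef("first_symptom_date", "date", required=True),
                AttributeDef("symptom_description", "text"),
                AttributeDef(
                    "age_at_onset", "computed",
                    formula=parse_formula(
                        "years_between(first_symptom_date, birth_date)"
                    ),
                ),
            ),
        ),
        ActivityDef(
            "family_history",
            "Family History",
            (
                AttributeDef(
                    "family_members", "table",
                    columns=(
                        ("relative", "text"),
                        ("condition", "text"),
                        ("onset_year", "integer"),
                    ),
                    hint="One row per affected family member - add rows as needed",
                ),
            ),
        ),
        ActivityDef(
            "optic_neuritis",
            "Optic Neuritis Episode",
            (
                AttributeDef("eye_affected", "choice", choices=("left", "right", "both")),
                AttributeDef("visual_acuity", "real", min=0, max=2),
                AttributeDef("episode_date", "date"),
            ),
        ),
        ActivityDef(
            "myelitis",
            "Myelitis Episode",
            (
                AttributeDef("spinal_level", "choice",
                             choices=("cervical", "thoracic", "lumbar")),
                AttributeDef("severity_score", "integer", min=0, max=10),
                AttributeDef("episode_date", "date"),
            ),
        ),
        ActivityDef(
            "neurological_exam",
            "Neurological Examination",
            (
                AttributeDef("edss_score", "real", min=0, max=10,
                             hint="Expanded Disability Status Scale"),
                AttributeDef("exam_notes", "text"),
            ),
        ),
        ActivityDef(
            "mri_brain",
            "MRI Brain",
            (
                _yes_no("lesions_present"),
                AttributeDef("lesion_count", "integer", min=0, max=200),
                AttributeDef("exam_date", "date"),
            ),
        ),
        ActivityDef(
            "mri_spinal_cord",
            "MRI Spinal Cord",
            (
                _yes_no("extensive_lesion"),
                AttributeDef("segments_involved", "integer", min=0, max=30),
                AttributeDef("exam_date", "date"),
            ),
        ),
        ActivityDef(
            "csf_analysis",
            "CSF Analysis",
            (
                AttributeDef("white_cell_count", "integer", min=0, max=100000),
                AttributeDef("oligoclonal_bands", "choice", choices=("present", "absent")),
                AttributeDef("exam_date", "date"),
            ),
        ),
        ActivityDef(
            "aqp4_serology",
            "AQP4 Serology",
            (
                AttributeDef("aqp4_result", "choice",
                             choices=("positive", "negative", "indeterminate")),
                AttributeDef("titer", "real", min=0, max=100000),
                AttributeDef("exam_date", "date"),
            ),
        ),
        ActivityDef(
            "visual_evoked_potential",
            "Visual Evoked Potential",
            (
                AttributeDef("p100_latency_ms", "real", min=0, max=300),
                AttributeDef("exam_date", "date"),
            ),
        ),
        ActivityDef(
            "differential_diagnosis",
            "Differential Diagnosis",
            (
                _yes_no("multiple_sclerosis_excluded"),
                AttributeDef("notes", "text"),
            ),
        ),
        ActivityDef(
            "diagnosis",
            "Diagnosis",
            (
                AttributeDef("diagnosis", "choice", required=True,
                             choices=("nmo", "nmo_spectrum_disorder",
                                      "multiple_sclerosis", "other")),
                AttributeDef("diagnosis_date", "date", required=True),
            ),
        ),
        ActivityDef(
            "treatment",
            "Treatment",
            (
                AttributeDef("medication", "text", required=True),
                AttributeDef("dose_mg", "real", min=0, max=100000),
                AttributeDef("start_date", "date"),
            ),
        ),
        ActivityDef(
            "relapse_record",
            "Relapse Record",
            (
                AttributeDef(
                    "relapses", "table",
                    columns=(
                        ("relapse_date", "date"),
                        ("description", "text"),
                        ("severity", "integer"),
                    ),
                ),
            ),
        ),
        ActivityDef(
            "follow_up",
            "Follow Up",
            (
                AttributeDef("visit_date", "date", required=True),
                AttributeDef("edss_score", "real", min=0, max=10),
                AttributeDef("notes", "text"),
            ),
        ),
    )
    transitions = (
        Transition("identification", "first_symptoms"),
        Transition("identification", "family_history"),
        Transition("first_symptoms", "optic_neuritis"),
        Transition("first_symptoms", "myelitis"),
        Transition("optic_neuritis", "neurological_exam"),
        Transition("myelitis", "neurological_exam"),
        Transition("family_history", "neurological_exam"),
        Transition("neurological_exam", "mri_brain"),
        Transition("neurological_exam", "mri_spinal_cord"),
        Transition("mri_brain", "csf_analysis"),
        Transition("mri_spinal_cord", "csf_analysis"),
        Transition("csf_analysis", "aqp4_serology"),
        Transition("aqp4_serology", "visual_evoked_potential"),
        Transition("aqp4_serology", "differential_diagnosis"),
        Transition("visual_evoked_potential", "differential_diagnosis"),
        Transition("differential_diagnosis", "diagnosis"),
        Transition("diagnosis", "treatment"),
        Transition("treatment", "relapse_record"),
        Transition("treatment", "follow_up"),
        Transition("relapse_record", "follow_up"),
    )
    return WorkflowDefinition(
        workflow_id="nmo",
        name="Neuromyelitis Optica",
        version="1.0",
        activities=activities,
        transitions=transitions,
    )


def build_pcm() -> WorkflowDefinition:
    """Paracoccidioidomycosis: SAME-identified cases with yes/no batteries."""
    condition_battery = tuple(
        _yes_no(f"condition_{i:02d}") for i in range(1, 36)
    )
    disease_battery = tuple(
        _yes_no(f"disease_{i:02d}") for i in range(1, 30)
    )
    activities = (
        ActivityDef(
            "identification",
            "Identification",
            (
                AttributeDef("same_number", "integer", required=True, min=1,
                             hint="Unique hospital medical-history number (SAME)"),
                AttributeDef("protocol_number", "integer", min=1),
                AttributeDef("name", "text", required=True),
                AttributeDef("birth_date", "date"),
                AttributeDef("occupation", "text", example="farm worker"),
                AttributeDef("city", "text"),
            ),
        ),
        ActivityDef(
            "first_consultation",
            "First Consultation",
            (
                AttributeDef("consultation_date", "date", required=True),
                AttributeDef("major_complaints", "text"),
            )
            + condition_battery
            + (AttributeDef("other_conditions", "text",
                            hint="Conditions not covered by the battery"),)
            + disease_battery
            + (AttributeDef("other_diseases", "text",
                            hint="Present/previous diseases not covered"),),
        ),
        ActivityDef(
            "respiratory_exam",
            "Respiratory System Exam",
            (
                _yes_no("alterations_present"),
                AttributeDef("findings", "text"),
                AttributeDef("exam_date", "date"),
            ),
        ),
        ActivityDef(
            "cardiovascular_exam",
            "Cardiovascular System Exam",
            (
                _yes_no("alterations_present"),
                AttributeDef("findings", "text"),
                AttributeDef("exam_date", "date"),
            ),
        ),
        ActivityDef(
            "digestive_exam",
            "Digestive System Exam",
            (
                _yes_no("alterations_present"),
                AttributeDef("findings", "text"),
                AttributeDef("exam_date", "date"),
            ),
        ),
        ActivityDef(
            "diagnosis_and_prescriptions",
            "Diagnostic Hypothesis, Exams and Prescriptions",
            (
                AttributeDef("diagnostic_hypothesis", "text", required=True),
                AttributeDef("exams_requested", "text"),
                AttributeDef("prescriptions", "text"),
            ),
        ),
    )
    transitions = (
        Transition("identification", "first_consultation"),
        Transition("first_consultation", "respiratory_exam"),
        Transition("first_consultation", "cardiovascular_exam"),
        Transition("first_consultation", "digestive_exam"),
        Transition("respiratory_exam", "diagnosis_and_prescriptions"),
        Transition("cardiovascular_exam", "diagnosis_and_prescriptions"),
        Transition("digestive_exam", "diagnosis_and_prescriptions"),
    )
    return WorkflowDefinition(
        workflow_id="pcm",
        name="Paracoccidioidomycosis",
        version="1.0",
        activities=activities,
        transitions=transitions,
    )


def build_ald() -> WorkflowDefinition:
    """Adrenoleukodystrophy: 9 activities, extensible registries, suggestions."""
    registries = {
        "ald_treatments": RegistryDef(
            "ald_treatments",
            entries=(
                "Lorenzo's oil",
                "Hematopoietic stem cell transplantation",
                "Adrenal hormone replacement",
            ),
            extensible=True,
        ),
        "ald_symptoms": RegistryDef(
            "ald_symptoms",
            entries=("Fatigue", "Leg Pain"),
            extensible=True,
        ),
    }
    activities = (
        ActivityDef(
            "diagnosis_information",
            "Diagnosis Information",
            (
                AttributeDef("patient_initials", "text", required=True, example="J.S."),
                AttributeDef("birth_date", "date", required=True),
                AttributeDef("place_of_birth", "text"),
                AttributeDef("previous_record_number", "integer", min=0),
                AttributeDef("genotype", "text"),
                AttributeDef("first_symptom_date", "date"),
                AttributeDef("first_symptom_description", "text"),
                AttributeDef("vlcfa_c26_umol_l", "real", min=0, max=20,
                             hint="Very-long-chain fatty acid C26:0 plasma level"),
                AttributeDef(
                    "age_at_first_symptom", "computed",
                    formula=parse_formula(
                        "years_between(first_symptom_date, birth_date)"
                    ),
                ),
            ),
        ),
        ActivityDef(
            "treatment",
            "Treatment",
            (
                AttributeDef("treatment", "register", registry="ald_treatments",
                             hint="Pick a pre-built treatment or register a new one"),
                AttributeDef("start_date", "date"),
            ),
        ),
        ActivityDef(
            "symptoms",
            "Symptoms",
            (
                AttributeDef("symptom", "register", registry="ald_symptoms"),
                AttributeDef("onset_date", "date"),
            ),
        ),
        ActivityDef(
            "clinical_evolution",
            "Clinical Evolution",
            (
                AttributeDef("visit_date", "date", required=True),
                AttributeDef("disability_score", "real", min=0, max=10),
                AttributeDef("clinical_notes", "text"),
            ),
        ),
        ActivityDef(
            "mri_encephalon",
            "MRI Encephalon",
            (
                AttributeDef("loes_score", "real", min=0, max=34),
                _yes_no("white_matter_lesions"),
                AttributeDef("exam_date", "date"),
            ),
        ),
        ActivityDef(
            "adrenal_function_test",
            "Adrenal Function Test",
            (
                AttributeDef("cortisol_basal_ug_dl", "real", min=0, max=100),
                AttributeDef("acth_pg_ml", "real", min=0, max=5000),
                AttributeDef("exam_date", "date"),
            ),
        ),
        ActivityDef(
            "neurological_examination",
            "Neurological Examination",
            (
                _yes_no("motor_deficit"),
                AttributeDef("exam_date", "date"),
                AttributeDef("exam_notes", "text"),
            ),
        ),
        ActivityDef(
            "mri_spinal_cord",
            "MRI Spinal Cord",
            (
                _yes_no("atrophy_present"),
                AttributeDef("exam_date", "date"),
            ),
        ),
        ActivityDef(
            "other_information",
            "Other Information",
            (AttributeDef("annotations", "text"),),
        ),
    )
    transitions = (
        Transition("diagnosis_information", "treatment"),
        Transition("treatment", "symptoms"),
        Transition("symptoms", "clinical_evolution"),
        Transition("clinical_evolution", "mri_encephalon"),
        Transition("clinical_evolution", "adrenal_function_test"),
        Transition("clinical_evolution", "neurological_examination"),
        Transition("clinical_evolution", "mri_spinal_cord"),
        Transition("mri_encephalon", "other_information"),
        Transition("adrenal_function_test", "other_information"),
        Transition("neurological_examination", "other_information"),
        Transition("mri_spinal_cord", "other_information"),
    )
    rules = (
        SuggestionRule(
            rule_id="elevated_vlcfa",
            source_activity="diagnosis_information",
            condition=parse_formula("vlcfa_c26_umol_l > 1.3"),
            suggested_activities=("treatment",),
        ),
        SuggestionRule(
            rule_id="low_cortisol",
            source_activity="adrenal_function_test",
            condition=parse_formula("cortisol_basal_ug_dl < 5"),
            suggested_activities=("mri_spinal_cord", "other_information"),
        ),
    )
    return WorkflowDefinition(
        workflow_id="ald",
        name="Adrenoleukodystrophy",
        version="1.0",
        activities=activities,
        transitions=transitions,
        registries=registries,
        suggestion_rules=rules,
    )


BUILDERS = {"nmo": build_nmo, "pcm": build_pcm, "ald": build_ald}
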