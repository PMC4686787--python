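<?xml version='1.0' encoding='UTF-8'?>
<!--
Adrenoleukodystrophy protocol fixture. The 9-activity structure, the
extensible treatment/symptom registries (defaults Fatigue, Leg Pain)
and the suggestion feature are published facts; attribute details are
reconstructions for testing.
-->
<Package xmlns="http://www.wfmc.org/2008/XPDL2.1" Id="ald" Name="Adrenoleukodystrophy">
  <PackageHeader>
    <XPDLVersion>2.1</XPDLVersion>
    <Vendor>fluxcase</Vendor>
  </PackageHeader>
  <ExtendedAttributes>
    <ExtendedAttribute Name="FLUX_REGISTRY" Value="NAME=ald_treatments;EXTENSIBLE=true;ENTRIES=Lorenzo's oil,Hematopoietic stem cell transplantation,Adrenal hormone replacement"/>
    <ExtendedAttribute Name="FLUX_REGISTRY" Value="NAME=ald_symptoms;EXTENSIBLE=true;ENTRIES=Fatigue,Leg Pain"/>
    <ExtendedAttribute Name="FLUX_SUGGEST" Value="ID=elevated_vlcfa;SOURCE=diagnosis_information;CONDITION=vlcfa_c26_umol_l &gt; 1.3;SUGGEST=treatment"/>
    <ExtendedAttribute Name="FLUX_SUGGEST" Value="ID=low_cortisol;SOURCE=adrenal_function_test;CONDITION=cortisol_basal_ug_dl &lt; 5;SUGGEST=mri_spinal_cord,other_information"/>
  </ExtendedAttributes>
  <WorkflowProcesses>
    <WorkflowProcess Id="ald" Name="Adrenoleukodystrophy">
      <RedefinableHeader>
        <Version>1.0</Version>
      </RedefinableHeader>
      <Activities>
        <Activity Id="diagnosis_information" Name="Diagnosis Information">
          <ExtendedAttributes>
            <ExtendedAttribute Name="FLUX_FIELD" Value="NAME=patient_initials;KIND=text;REQUIRED=true;EXAMPLE=J.S."/>
            <ExtendedAttribute Name="FLUX_FIELD" Value="NAME=birth_date;KIND=date;REQUIRED=true"/>
            <ExtendedAttribute Name="FLUX_FIELD" Value="NAME=place_of_birth;KIND=text"/>
            <ExtendedAttribute Name="FLUX_FIELD" Value="NAME=previous_record_number;KIND=integer;MIN=0"/>
            <ExtendedAttribute Name="FLUX_FIELD" Value="NAME=genotype;KIND=text"/>
            <ExtendedAttribute Name="FLUX_FIELD" Value="NAME=first_symptom_date;KIND=date"/>
            <ExtendedAttribute Name="FLUX_FIELD" Value="NAME=first_symptom_description;KIND=text"/>
            <ExtendedAttribute Name="FLUX_FIELD" Value="NAME=vlcfa_c26_umol_l;KIND=real;MIN=0;MAX=20;HINT=Very-long-chain fatty acid C26:0 plasma level"/>
            <ExtendedAttribute Name="FLUX_FIELD" Value="NAME=age_at_first_symptom;KIND=computed;FORMULA=years_between(first_symptom_date, birth_date)"/>
          </ExtendedAttributes>
        </Activity>
        <Activity Id="treatment" Name="Treatment">
          <ExtendedAttributes>
            <ExtendedAttribute Name="FLUX_FIELD" Value="NAME=treatment;KIND=register;REGISTRY=ald_treatments;HINT=Pick a pre-built treatment or register a new one"/>
            <ExtendedAttribute Name="FLUX_FIELD" Value="NAME=start_date;KIND=date"/>
          </ExtendedAttributes>
        </Activity>
        <Activity Id="symptoms" Name="Symptoms">
          <ExtendedAttributes>
            <ExtendedAttribute Name="FLUX_FIELD" Value="NAME=symptom;KIND=register;REGISTRY=ald_symptoms"/>
            <ExtendedAttribute Name="FLUX_FIELD" Value="NAME=onset_date;KIND=date"/>
          </ExtendedAttributes>
        </Activity>
        <Activity Id="clinical_evolution" Name="Clinical Evolution">
          <ExtendedAttributes>
            <ExtendedAttribute Name="FLUX_FIELD" Value="NAME=visit_date;KIND=date;REQUIRED=true"/>
            <ExtendedAttribute Name="FLUX_FIELD" Value="NAME=disability_score;KIND=real;MIN=0;MAX=10"/>
            <ExtendedAttribute Name="FLUX_FIELD" Value="NAME=clinical_notes;KIND=text"/>
          </ExtendedAttributes>
        </Activity>
        <Activity Id="mri_encephalon" Name="MRI Encephalon">
          <ExtendedAttributes>
            <ExtendedAttribute Name="FLUX_FIELD" Value="NAME=loes_score;KIND=real;MIN=0;MAX=34"/>
            <ExtendedAttribute Name="FLUX_FIELD" Value="NAME=white_matter_lesions;KIND=choice;CHOICES=yes,no"/>
            <ExtendedAttribute Name="FLUX_FIELD" Value="NAME=exam_date;KIND=date"/>
          </ExtendedAttributes>
        </Activity>
        <Activity Id="adrenal_function_test" Name="Adrenal Function Test">
          <ExtendedAttributes>
            <ExtendedAttribute Name="FLUX_FIELD" Value="NAME=cortisol_basal_ug_dl;KIND=real;MIN=0;MAX=100"/>
            <ExtendedAttribute Name="FLUX_FIELD" Value="NAME=acth_pg_ml;KIND=real;MIN=0;MAX=5000"/>
            <ExtendedAttribute Name="FLUX_FIELD" Value="NAME=exam_date;KIND=date"/>
          </ExtendedAttributes>
        </Activity>
        <Activity Id="neurological_examination" Name="Neurological Examination">
          <ExtendedAttributes>
            <ExtendedAttribute Name="FLUX_FIELD" Value="NAME=motor_deficit;KIND=choice;CHOICES=yes,no"/>
            <ExtendedAttribute Name="FLUX_FIELD" Value="NAME=exam_date;KIND=date"/>
            <ExtendedAttribute Name="FLUX_FIELD" Value="NAME=exam_notes;KIND=text"/>
          </ExtendedAttributes>
        </Activity>
        <Activity Id="mri_spinal_cord" Name="MRI Spinal Cord">
          <ExtendedAttributes>
            <ExtendedAttribute Name="FLUX_FIELD" Value="NAME=atrophy_present;KIND=choice;CHOICES=yes,no"/>
            <ExtendedAttribute Name="FLUX_FIELD" Value="NAME=exam_date;KIND=date"/>
          </ExtendedAttributes>
        </Activity>
        <Activity Id="other_information" Name="Other Information">
          <ExtendedAttributes>
            <ExtendedAttribute Name="FLUX_FIELD" Value="NAME=annotations;KIND=text"/>
          </ExtendedAttributes>
        </Activity>
      </Activities>
      <Transitions>
        <Transition Id="t1" From="diagnosis_information" To="treatment"/>
        <Transition Id="t2" From="treatment" To="symptoms"/>
        <Transition Id="t3" From="symptoms" To="clinical_evolution"/>
        <Transition Id="t4" From="clinical_evolution" To="mri_encephalon"/>
        <Transition Id="t5" From="clinical_evolution" To="adrenal_function_test"/>
        <Transition Id="t6" From="clinical_evolution" To="neurological_examination"/>
        <Transition Id="t7" From="clinical_evolution" To="mri_spinal_cord"/>
        <Transition Id="t8" From="mri_encephalon" To="other_information"/>
        <Transition Id="t9" From="adrenal_function_test" To="other_information"/>
        <Transition Id="t10" From="neurological_examination" To="other_information"/>
        <Transition Id="t11" From="mri_spinal_cord" To="other_information"/>
      </Transitions>
    </WorkflowProcess>
  </WorkflowProcesses>
</Package>
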