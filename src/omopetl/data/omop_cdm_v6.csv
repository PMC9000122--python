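table,column,sql_type,nullable,is_primary_key,fk_table,fk_column
person,person_id,bigint,0,1,,
person,gender_concept_id,integer,0,0,,
person,year_of_birth,integer,0,0,,
person,month_of_birth,integer,1,0,,
person,day_of_birth,integer,1,0,,
person,birth_datetime,timestamp,1,0,,
person,death_datetime,timestamp,1,0,,
person,race_concept_id,integer,0,0,,
person,ethnicity_concept_id,integer,0,0,,
person,location_id,bigint,1,0,,
person,provider_id,bigint,1,0,,
person,care_site_id,bigint,1,0,,
person,person_source_value,varchar(50),1,0,,
person,gender_source_value,varchar(50),1,0,,
person,gender_source_concept_id,integer,0,0,,
person,race_source_value,varchar(50),1,0,,
person,race_source_concept_id,integer,0,0,,
person,ethnicity_source_value,varchar(50),1,0,,
person,ethnicity_source_concept_id,integer,0,0,,
observation_period,observation_period_id,bigint,0,1,,
observation_period,person_id,bigint,0,0,person,person_id
observation_period,observation_period_start_date,date,0,0,,
observation_period,observation_period_end_date,date,0,0,,
observation_period,period_type_concept_id,integer,0,0,,
visit_occurrence,visit_occurrence_id,bigint,0,1,,
visit_occurrence,person_id,bigint,0,0,person,person_id
visit_occurrence,visit_concept_id,integer,0,0,,
visit_occurrence,visit_start_date,date,1,0,,
visit_occurrence,visit_start_datetime,timestamp,0,0,,
visit_occurrence,visit_end_date,date,1,0,,
visit_occurrence,visit_end_datetime,timestamp,0,0,,
visit_occurrence,visit_type_concept_id,integer,0,0,,
visit_occurrence,provider_id,bigint,1,0,,
visit_occurrence,care_site_id,bigint,1,0,,
visit_occurrence,visit_source_value,varchar(50),1,0,,
visit_occurrence,visit_source_concept_id,integer,0,0,,
visit_occurrence,admitted_from_concept_id,integer,0,0,,
visit_occurrence,admitted_from_source_value,varchar(50),1,0,,
visit_occurrence,discharge_to_concept_id,integer,0,0,,
visit_occurrence,discharge_to_source_value,varchar(50),1,0,,
visit_occurrence,preceding_visit_occurrence_id,bigint,1,0,visit_occurrence,visit_occurrence_id
condition_occurrence,condition_occurrence_id,bigint,0,1,,
condition_occurrence,person_id,bigint,0,0,person,person_id
condition_occurrence,condition_concept_id,integer,0,0,,
condition_occurrence,condition_start_date,date,1,0,,
condition_occurrence,condition_start_datetime,timestamp,0,0,,
condition_occurrence,condition_end_date,date,1,0,,
condition_occurrence,condition_end_datetime,timestamp,1,0,,
condition_occurrence,condition_type_concept_id,integer,0,0,,
condition_occurrence,condition_status_concept_id,integer,0,0,,
condition_occurrence,stop_reason,varchar(20),1,0,,
condition_occurrence,provider_id,bigint,1,0,,
condition_occurrence,visit_occurrence_id,bigint,1,0,visit_occurrence,visit_occurrence_id
condition_occurrence,visit_detail_id,bigint,1,0,,
condition_occurrence,condition_source_value,varchar(50),1,0,,
condition_occurrence,condition_source_concept_id,integer,0,0,,
condition_occurrence,condition_status_source_value,varchar(50),1,0,,
drug_exposure,drug_exposure_id,bigint,0,1,,
drug_exposure,person_id,bigint,0,0,person,person_id
drug_exposure,drug_concept_id,integer,0,0,,
drug_exposure,drug_exposure_start_date,date,1,0,,
drug_exposure,drug_exposure_start_datetime,timestamp,0,0,,
drug_exposure,drug_exposure_end_date,date,1,0,,
drug_exposure,drug_exposure_end_datetime,timestamp,0,0,,
drug_exposure,verbatim_end_date,date,1,0,,
drug_exposure,drug_type_concept_id,integer,0,0,,
drug_exposure,stop_reason,varchar(20),1,0,,
drug_exposure,refills,integer,1,0,,
drug_exposure,quantity,numeric,1,0,,
drug_exposure,days_supply,integer,1,0,,
drug_exposure,sig,text,1,0,,
drug_exposure,route_concept_id,integer,0,0,,
drug_exposure,lot_number,varchar(50),1,0,,
drug_exposure,provider_id,bigint,1,0,,
drug_exposure,visit_occurrence_id,bigint,1,0,visit_occurrence,visit_occurrence_id
drug_exposure,visit_detail_id,bigint,1,0,,
drug_exposure,drug_source_value,varchar(50),1,0,,
drug_exposure,drug_source_concept_id,integer,0,0,,
drug_exposure,route_source_value,varchar(50),1,0,,
drug_exposure,dose_unit_source_value,varchar(50),1,0,,
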