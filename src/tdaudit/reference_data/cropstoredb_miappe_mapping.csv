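schema_field,concept,attribute,note
project.project_id,investigation,investigation unique id,synthetic reconstruction of a CropStoreDB-style schema mapping
project.project_name,investigation,investigation title,
project.description,investigation,investigation description,
project.metadata_standard,investigation,miappe version,
plant_trials.trial_id,study,study unique id,plant_trials holds location and design metadata
plant_trials.trial_name,study,study title,
plant_trials.description,study,study description,
plant_trials.start_date,study,start date of study,
plant_trials.end_date,study,end date of study,
plant_trials.institution,study,contact institution,
plant_trials.country,study,geographic location (country),
plant_trials.site_name,study,experimental site name,
plant_trials.latitude,study,geographic location (latitude),
plant_trials.longitude,study,geographic location (longitude),
plant_trials.trial_design,study,description of the experimental design,
plant_trials.facility_type,study,type of growth facility,
plant_trials.plot_description,study,observation unit description,
people.full_name,person,person name,
people.email,person,person email,
people.role,person,person role,
people.institution,person,person affiliation,
accessions.accession_id,biological material,biological material id,
accessions.taxon,biological material,organism,
accessions.genus,biological material,genus,
accessions.species,biological material,species,
accessions.source_id,biological material,material source id,
plots.plot_id,observation unit,observation unit id,
plots.plot_type,observation unit,observation unit type,
samples.sample_id,sample,sample id,
samples.growth_stage,sample,plant structure development stage,
samples.organ,sample,plant anatomical entity,
samples.collection_date,sample,collection date,
trait_descriptors.co_identifier,observed variable,variable id,cross-reference to the Crop Ontology identifier
trait_descriptors.descriptor_name,observed variable,variable name,
trait_descriptors.trait_name,observed variable,trait,
trait_descriptors.method,observed variable,method,
trait_descriptors.scale,observed variable,scale,
plant_trials.design_factors,experimental factor,experimental factor type,factor values are not recorded separately
scoring_data.raw_value,unmapped,,trait scores live in the data tables rather than MIAPPE metadata
plant_trials.notes,unmapped,,free-text remarks with no MIAPPE counterpart
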