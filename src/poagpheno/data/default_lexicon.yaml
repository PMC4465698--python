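# Default code sets and term lists parameterizing the POAG phenotyping
# algorithm.  Every key here can be overridden by a user config file passed
# to load_lexicon / the --lexicon CLI flag.
#
# The glaucoma-medication and hypertension-medication lists are documented
# RECONSTRUCTIONS covering the standard drug classes, not a transcription of
# any institutional formulary.

poag_icd9: "365.11"
glaucoma_icd9_prefix: "365."

# ophthalmology exam / fundus photography CPT codes
ophtho_cpt:
  - "92002"
  - "92004"
  - "92012"
  - "92014"
  - "92250"

# evaluation & management (general clinic) CPT range 99201-99215
general_clinic_cpt:
  - "99201"
  - "99202"
  - "99203"
  - "99204"
  - "99205"
  - "99211"
  - "99212"
  - "99213"
  - "99214"
  - "99215"

# the subset of ophtho codes accepted as fundus/exam evidence for potential cases
fundus_cpt:
  - "92012"
  - "92014"
  - "92250"

# glaucoma spelling variants searched in free text (order preserved)
glaucoma_spelling_variants:
  - glaucoma
  - glaucome
  - glocoma
  - gloucoma
  - gluacoma
  - glucoma
  - glycoma

# terms for the secondary free-text review of algorithm-identified controls
control_review_terms:
  - glaucoma
  - fundus
  - opth
  - ophth
  - vision

# topical/systemic glaucoma medications (reconstruction: prostaglandin
# analogs, beta-blockers, alpha agonists, carbonic anhydrase inhibitors,
# miotics, and common combination products)
glaucoma_medications:
  - latanoprost
  - bimatoprost
  - travoprost
  - tafluprost
  - timolol
  - betaxolol
  - levobunolol
  - carteolol
  - brimonidine
  - apraclonidine
  - dorzolamide
  - brinzolamide
  - acetazolamide
  - methazolamide
  - pilocarpine
  - carbachol
  - echothiophate
  - xalatan
  - lumigan
  - travatan
  - timoptic
  - alphagan
  - trusopt
  - azopt
  - cosopt
  - combigan
  - diamox
  - pilopine

# surgical-procedure phrases supporting a definite POAG case when found in a
# surgical report
poag_surgery_phrases:
  - argon laser trabeculoplasty
  - selective laser trabeculoplasty
  - micropulse laser trabeculoplasty
  - ex-press mini glaucoma shunt

# written-diagnosis phrases for glaucoma subtypes other than POAG
other_subtype_labels:
  uveitic:
    - uveitic glaucoma
  chronic_angle_closure:
    - chronic angle closure glaucoma
    - chronic angle-closure glaucoma
    - closed-angle glaucoma
    - angle closure glaucoma
  pediatric:
    - pediatric glaucoma
    - congenital glaucoma
  neovascular:
    - neovascular glaucoma
  steroid_responder:
    - glaucoma steroid responder
    - steroid responder
    - steroid-induced glaucoma

# phrases that never count toward case evidence
ambiguity_phrases:
  - advanced glaucoma
  - ocular hypertension
  - glaucoma suspect

# antihypertensive medications for the hypertension covariate (reconstruction:
# ACE inhibitors, ARBs, thiazides, calcium-channel and beta blockers, loop
# diuretics)
hypertension_medications:
  - lisinopril
  - enalapril
  - ramipril
  - captopril
  - losartan
  - valsartan
  - olmesartan
  - irbesartan
  - hydrochlorothiazide
  - chlorthalidone
  - amlodipine
  - nifedipine
  - diltiazem
  - verapamil
  - metoprolol
  - atenolol
  - carvedilol
  - labetalol
  - propranolol
  - furosemide
  - spironolactone
  - clonidine
  - hydralazine

# age / threshold / window parameters
case_min_age: 20          # eligibility requires age strictly over this
control_min_age: 40       # controls must be at least this old
sbp_threshold: 140        # mm Hg, strict >
dbp_threshold: 90         # mm Hg, strict >
covariate_window_days: 730
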