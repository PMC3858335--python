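entity_class	surface_form	canonical_id
ETHNICITY	caucasian	caucasian
ETHNICITY	caucasians	caucasian
ETHNICITY	white	caucasian
ETHNICITY	whites	caucasian
ETHNICITY	european	caucasian
ETHNICITY	europeans	caucasian
ETHNICITY	asian	asian
ETHNICITY	asians	asian
ETHNICITY	chinese	chinese
ETHNICITY	japanese	japanese
ETHNICITY	korean	korean
ETHNICITY	koreans	korean
ETHNICITY	african	african
ETHNICITY	africans	african
ETHNICITY	african american	african_american
ETHNICITY	african americans	african_american
ETHNICITY	hispanic	hispanic
ETHNICITY	hispanics	hispanic
EFFECT	increase	increase
EFFECT	increased	increase
EFFECT	elevated	increase
EFFECT	higher	increase
EFFECT	induction	increase
EFFECT	decrease	decrease
EFFECT	decreased	decrease
EFFECT	reduced	decrease
EFFECT	lower	decrease
EFFECT	impaired	decrease
EFFECT	deficient	decrease
EFFECT	nonfunctional	no_activity
EFFECT	inactive	no_activity
EFFECT	abolished	no_activity
NEGATION	no	no
NEGATION	not	not
NEGATION	neither	neither
NEGATION	without	without
NEGATION	lacked	lacked
NEGATION	lacking	lacking
NEGATION	absent	absent
NEGATION	never	never
CYP	debrisoquine hydroxylase	2D6
CYP	mephenytoin hydroxylase	2C19
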