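# Medical domain knowledge base: medical data-analysis tasks, medical data
# and the domain-specific descriptive algorithms for consistency analysis
# of physiological parameter dynamics.  Entities that also exist in the DM
# Core knowledge base (stub declarations below) unify with it on merging.
CLASS	MedicalData
CLASS	TaskRequirement
CLASS	DataCharacteristic
CLASS	DescriptiveModelingAlgorithm
CLASS	Modelling
OBJPROP	employs
OBJPROP	employedBy
OBJPROP	suitableFor
OBJPROP	hasInput
DATAPROPERTY	hasObjective
SUBCLASSOF	MedicalDataAnalysisTask	TaskRequirement
SUBCLASSOF	ConsistencyAnalysis	MedicalDataAnalysisTask
SUBCLASSOF	SurvivalAnalysis	MedicalDataAnalysisTask
SUBCLASSOF	ABS_Data	MedicalData
SUBCLASSOF	Continuous	DataCharacteristic
SUBCLASSOF	Missing_not_Random	DataCharacteristic
RESTRICTION	ConsistencyAnalysis	hasInput	some	MedicalData
RESTRICTION	ConsistencyAnalysis	employs	some	DescriptiveModelingAlgorithm
DATAPROP	ConsistencyAnalysis	hasObjective	consistency of parameter dynamics	string
SUBCLASSOF	CF_Algorithm	DescriptiveModelingAlgorithm
RESTRICTION	CF_Algorithm	suitableFor	some	ConsistencyAnalysis
RESTRICTION	CF_Algorithm	suitableFor	some	Continuous
RESTRICTION	CF_Algorithm	employedBy	some	Modelling
SUBCLASSOF	Kupershtokh_Mirkin_Trofimov_Algorithm	DescriptiveModelingAlgorithm
RESTRICTION	Kupershtokh_Mirkin_Trofimov_Algorithm	suitableFor	some	ConsistencyAnalysis
RESTRICTION	Kupershtokh_Mirkin_Trofimov_Algorithm	suitableFor	some	Continuous
RESTRICTION	Kupershtokh_Mirkin_Trofimov_Algorithm	employedBy	some	Modelling
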