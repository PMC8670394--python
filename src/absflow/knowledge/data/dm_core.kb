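# DM Core knowledge base: general data-mining knowledge used for algorithm
# selection -- algorithms, processes, characteristics, parameters and the
# INPUT sub-hierarchy describing data characteristics and task requirements.
CLASS	Algorithm
CLASS	Characteristics
CLASS	INPUT
CLASS	Parameter
CLASS	Process
CLASS	OutputModel
OBJPROP	hasPostprocess
OBJPROP	hasSubprocess
OBJPROP	hasInput
OBJPROP	hasOutput
OBJPROP	hasParameter
OBJPROP	hasCharacteristic
OBJPROP	hasMeasure
OBJPROP	suitableFor
OBJPROP	availableFor
OBJPROP	employs
OBJPROP	employedBy
DATAPROPERTY	hasMinLength
DATAPROPERTY	has_Samples
DATAPROPERTY	has_Labels
# ---------------------------------------------------------------- INPUT
SUBCLASSOF	DataCharacteristic	INPUT
SUBCLASSOF	TaskRequirement	INPUT
SUBCLASSOF	DataWithClassImbalance	DataCharacteristic
SUBCLASSOF	DataWithMissingValue	DataCharacteristic
SUBCLASSOF	DataWithoutMissingValue	DataCharacteristic
SUBCLASSOF	Continuous	DataCharacteristic
SUBCLASSOF	Discrete	DataCharacteristic
SUBCLASSOF	Missing_not_Random	DataCharacteristic
SUBCLASSOF	Missing_at_Random	DataCharacteristic
SUBCLASSOF	Missing_Completely_at_Random	DataCharacteristic
SUBCLASSOF	SmallSizeDataset	DataCharacteristic
SUBCLASSOF	HighDimensionalData	DataCharacteristic
SUBCLASSOF	DataWithReducedDimension	DataCharacteristic
SUBCLASSOF	TimeSeriesDataset	DataCharacteristic
SUBCLASSOF	LongTSDataset	TimeSeriesDataset
DATAPROP	LongTSDataset	hasMinLength	700	integer
SUBCLASSOF	BinaryClassification	TaskRequirement
# --------------------------------------------- algorithm characteristics
SUBCLASSOF	ToleranceToClassImbalance	Characteristics
SUBCLASSOF	HandlingOfClassificationCosts	Characteristics
SUBCLASSOF	BiasVarianceProfile	Characteristics
RESTRICTION	ToleranceToClassImbalance	suitableFor	some	DataWithClassImbalance
# ------------------------------------------------------- CRISP-DM stages
SUBCLASSOF	DataMiningStage	Process
SUBCLASSOF	BusinessUnderstanding	DataMiningStage
SUBCLASSOF	DataUnderstanding	DataMiningStage
SUBCLASSOF	DataPreparation	DataMiningStage
SUBCLASSOF	DataProcessing	DataMiningStage
SUBCLASSOF	Evaluation	DataMiningStage
SUBCLASSOF	Deployment	DataMiningStage
RESTRICTION	BusinessUnderstanding	hasPostprocess	some	DataUnderstanding
RESTRICTION	DataUnderstanding	hasPostprocess	some	DataPreparation
RESTRICTION	DataPreparation	hasPostprocess	some	DataProcessing
RESTRICTION	DataProcessing	hasPostprocess	some	Evaluation
RESTRICTION	Evaluation	hasPostprocess	some	Deployment
# ----------------------------------------------- stage sub-processes
SUBCLASSOF	ApplicationObjectivesIdentification	Process
SUBCLASSOF	ApplicationResourcesAssessment	Process
SUBCLASSOF	DataMiningGoalsIdentification	Process
RESTRICTION	BusinessUnderstanding	hasSubprocess	some	ApplicationObjectivesIdentification
RESTRICTION	BusinessUnderstanding	hasSubprocess	some	ApplicationResourcesAssessment
RESTRICTION	BusinessUnderstanding	hasSubprocess	some	DataMiningGoalsIdentification
SUBCLASSOF	DataMiningGoalsDescription	OutputModel
SUBCLASSOF	DataMiningSuccessCriteriaDescription	OutputModel
RESTRICTION	DataMiningGoalsIdentification	hasOutput	some	DataMiningGoalsDescription
RESTRICTION	DataMiningGoalsIdentification	hasOutput	some	DataMiningSuccessCriteriaDescription
SUBCLASSOF	DataDescription	Process
SUBCLASSOF	DataQualityVerification	Process
RESTRICTION	DataUnderstanding	hasSubprocess	some	DataDescription
RESTRICTION	DataUnderstanding	hasSubprocess	some	DataQualityVerification
SUBCLASSOF	DataDescriptionReport	OutputModel
SUBCLASSOF	DataQualityReport	OutputModel
RESTRICTION	DataDescription	hasOutput	some	DataDescriptionReport
RESTRICTION	DataQualityVerification	hasOutput	some	DataQualityReport
SUBCLASSOF	SelectData	Process
SUBCLASSOF	CleanData	Process
SUBCLASSOF	ConstructData	Process
SUBCLASSOF	IntegrateData	Process
SUBCLASSOF	FormatData	Process
RESTRICTION	DataPreparation	hasSubprocess	some	SelectData
RESTRICTION	DataPreparation	hasSubprocess	some	CleanData
RESTRICTION	DataPreparation	hasSubprocess	some	ConstructData
RESTRICTION	DataPreparation	hasSubprocess	some	IntegrateData
RESTRICTION	DataPreparation	hasSubprocess	some	FormatData
SUBCLASSOF	MissingValueProcessing	CleanData
SUBCLASSOF	DimensionReduction	ConstructData
RESTRICTION	MissingValueProcessing	hasInput	some	DataWithMissingValue
RESTRICTION	MissingValueProcessing	hasOutput	some	DataWithoutMissingValue
RESTRICTION	DimensionReduction	hasInput	some	HighDimensionalData
RESTRICTION	DimensionReduction	hasOutput	some	DataWithReducedDimension
SUBCLASSOF	Modelling	Process
RESTRICTION	DataProcessing	hasSubprocess	some	Modelling
RESTRICTION	Modelling	hasInput	some	DataWithoutMissingValue
RESTRICTION	Modelling	hasOutput	some	OutputModel
SUBCLASSOF	ResultsSummarization	Process
RESTRICTION	Evaluation	hasSubprocess	some	ResultsSummarization
SUBCLASSOF	ResultsSummaryReport	OutputModel
RESTRICTION	ResultsSummarization	hasOutput	some	ResultsSummaryReport
# ----------------------------------------------------------- algorithms
SUBCLASSOF	InductionAlgorithm	Algorithm
SUBCLASSOF	ModelingAlgorithm	InductionAlgorithm
SUBCLASSOF	ClassificationModelingAlgorithm	ModelingAlgorithm
SUBCLASSOF	ClusteringModelingAlgorithm	ModelingAlgorithm
SUBCLASSOF	DescriptiveModelingAlgorithm	ModelingAlgorithm
SUBCLASSOF	ImputationAlgorithm	Algorithm
SUBCLASSOF	DimensionReductionAlgorithm	Algorithm
SUBCLASSOF	PCA	DimensionReductionAlgorithm
RESTRICTION	PCA	employedBy	some	DimensionReduction
SUBCLASSOF	SVC_Algorithm	ClassificationModelingAlgorithm
SUBCLASSOF	CapacityParameter	Parameter
SUBCLASSOF	KernelTypeParameter	Parameter
RESTRICTION	SVC_Algorithm	hasParameter	some	CapacityParameter
RESTRICTION	SVC_Algorithm	hasParameter	some	KernelTypeParameter
SUBCLASSOF	BayesianAlgorithm	ClassificationModelingAlgorithm
RESTRICTION	BayesianAlgorithm	hasCharacteristic	some	ToleranceToClassImbalance
RESTRICTION	BayesianAlgorithm	hasCharacteristic	some	HandlingOfClassificationCosts
RESTRICTION	BayesianAlgorithm	hasCharacteristic	some	BiasVarianceProfile
SUBCLASSOF	KMeans_Algorithm	ClusteringModelingAlgorithm
SUBCLASSOF	KNN_Algorithm	Algorithm
RESTRICTION	KNN_Algorithm	suitableFor	some	SmallSizeDataset
SUBCLASSOF	Measure	Parameter
SUBCLASSOF	Euclidean_Distance	Measure
SUBCLASSOF	NeighborCountParameter	Parameter
SUBCLASSOF	KNN_Imputation_ED	ImputationAlgorithm
RESTRICTION	KNN_Imputation_ED	employs	some	KNN_Algorithm
RESTRICTION	KNN_Imputation_ED	hasMeasure	some	Euclidean_Distance
RESTRICTION	KNN_Imputation_ED	hasParameter	some	NeighborCountParameter
RESTRICTION	KNN_Imputation_ED	suitableFor	some	Continuous
RESTRICTION	KNN_Imputation_ED	suitableFor	some	Missing_not_Random
RESTRICTION	KNN_Imputation_ED	employedBy	some	MissingValueProcessing
SUBCLASSOF	Mean_Imputation	ImputationAlgorithm
RESTRICTION	Mean_Imputation	suitableFor	some	Continuous
RESTRICTION	Mean_Imputation	suitableFor	some	Missing_Completely_at_Random
RESTRICTION	Mean_Imputation	employedBy	some	MissingValueProcessing
SUBCLASSOF	Regression_Imputation	ImputationAlgorithm
RESTRICTION	Regression_Imputation	suitableFor	some	Continuous
RESTRICTION	Regression_Imputation	suitableFor	some	Missing_at_Random
RESTRICTION	Regression_Imputation	employedBy	some	MissingValueProcessing
# ------------------------------------------------------- output models
SUBCLASSOF	BinaryClassificationModel	OutputModel
RESTRICTION	BinaryClassificationModel	availableFor	some	BinaryClassification
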