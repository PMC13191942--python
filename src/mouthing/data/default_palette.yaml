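# Default coding palette: three parallel channels (object mouthed, location,
# risk context). Within each channel, states are listed in descending risk
# priority: when two states are observed simultaneously the earlier one wins.
# The twelve high-risk objects come first; the relative order of the remaining
# object buttons is a package convention (see docs/methods.md).
version: "1.0"
expected_counts:
  OBJECT: 35
  LOCATION: 8
  CONTEXT: 6
channels:
  OBJECT:
    - HumanFeces
    - AnimalFeces
    - ToiletPotty
    - DrainageStagnantWater
    - RiverOceanWater
    - OtherEnvironmentalWater
    - SoilDirtGrass
    - FloorGround
    - ConcreteBitumenStone
    - TrashCan
    - PlantsLeaves
    - Animal
    - OtherPeoplesMouth
    - OtherPeoplesHandSkin
    - OwnHand
    - OwnSkin
    - PlasticVinylRubber
    - Wood
    - Cloth
    - CardboardPaper
    - CeramicGlass
    - Metal
    - BenchtopSurface
    - PlantFiberMat
    - Wall
    - Ball
    - PhoneTablet
    - OtherMixedObject
    - Rice
    - FishMeatEgg
    - FruitVegetable
    - DryFood
    - LiquidFood
    - OtherFood
    - DrinkingWater
    - Nothing
    - NotInView
  LOCATION:
    - OutdoorCommunal
    - OutsideOtherHouse
    - OutsideHome
    - PorchOtherHouse
    - PorchHome
    - IndoorCommunal
    - IndoorOtherHouse
    - IndoorHome
  CONTEXT:
    - AroundFeces
    - AroundAnimal
    - EnvironmentalWater
    - Eating
    - Handwashing
    - NoRisk
sentinels:
  nothing: Nothing
  not_in_view: NotInView
object_groups:
  high_risk:
    - HumanFeces
    - AnimalFeces
    - ToiletPotty
    - SoilDirtGrass
    - TrashCan
    - FloorGround
    - Animal
    - PlantsLeaves
    - ConcreteBitumenStone
    - DrainageStagnantWater
    - RiverOceanWater
    - OtherEnvironmentalWater
  other_hand_skin:
    - OtherPeoplesMouth
    - OtherPeoplesHandSkin
  own_hand_skin:
    - OwnHand
    - OwnSkin
  fomite:
    - PlasticVinylRubber
    - Wood
    - Cloth
    - CardboardPaper
    - CeramicGlass
    - Metal
    - BenchtopSurface
    - PlantFiberMat
    - Wall
    - Ball
    - PhoneTablet
    - OtherMixedObject
  food:
    - Rice
    - FishMeatEgg
    - FruitVegetable
    - DryFood
    - LiquidFood
    - OtherFood
    - DrinkingWater
high_risk_contexts:
  - AroundFeces
  - AroundAnimal
  - EnvironmentalWater
eating_context: Eating
outdoor_locations:
  - OutdoorCommunal
  - OutsideOtherHouse
  - OutsideHome
  - PorchOtherHouse
  - PorchHome
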